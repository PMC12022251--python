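"""Exception hierarchy for harvstat."""


class HarvstatError(Exception):
    """Base class for all harvstat errors."""


class SchemaError(HarvstatError):
    """A table does not conform to the canonical 16-column schema."""


class InvariantError(HarvstatError):
    """A record or geometry violates a data-model invariant."""


class CRSMismatchError(HarvstatError):
    """Two geospatial inputs are in different coordinate reference systems."""


class PipelineStageError(HarvstatError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
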