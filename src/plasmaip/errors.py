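"""Exception hierarchy for the plasmaip pipeline."""


class PlasmaIpError(Exception):
    """Base class for all plasmaip errors."""


class SchemaError(PlasmaIpError):
    """A table or config violates the expected schema (bad column, bad enum value,
    duplicated key, non-numeric intensity, ...)."""


class JoinError(PlasmaIpError):
    """LFQ matrix and IP metadata do not describe the same set of IPs."""


class PipelineError(PlasmaIpError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
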