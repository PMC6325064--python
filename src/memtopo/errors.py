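"""Exception types shared across the package."""


class MemtopoError(Exception):
    """Base class for all memtopo errors."""


class InvalidSpecError(MemtopoError, ValueError):
    """A surface / run specification is invalid (bad geometry, bad parameters)."""


class ContractError(MemtopoError, ValueError):
    """Inputs to an operation are mutually inconsistent (mismatched provenance)."""


class CatalogError(MemtopoError, KeyError):
    """An unknown fixture name was requested from the catalog."""


class StageError(MemtopoError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
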