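"""Exception types shared across the pipeline."""


class DeferDxError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DeferDxError):
    """A configuration value or distribution spec is invalid; names the field."""


class InsufficientPanelError(DeferDxError):
    """An image retains fewer than two reads after excluding a reader."""

    def __init__(self, image_ids, excluded_reader=None):
        self.image_ids = sorted(image_ids)
        self.excluded_reader = excluded_reader
        who = f" after excluding reader {excluded_reader!r}" if excluded_reader else ""
        super().__init__(
            f"{len(self.image_ids)} image(s) retain fewer than 2 reads{who}: "
            f"{self.image_ids[:10]}"
        )


class AlignmentError(DeferDxError):
    """Two per-image tables do not cover the same image set."""

    def __init__(self, message, missing=()):
        self.missing = sorted(missing)
        if self.missing:
            message = f"{message}: {self.missing[:10]}"
        super().__init__(message)


class AdjudicationError(DeferDxError):
    """A physician-AI disagreement has no second reviewer available."""

    def __init__(self, image_ids):
        self.image_ids = sorted(image_ids)
        super().__init__(
            "no second reviewer available for disagreeing image(s): "
            f"{self.image_ids[:10]}"
        )


class SchemaError(DeferDxError):
    """A CSV input violates the expected schema; names file, rows and column."""
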