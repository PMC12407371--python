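"""Exception types shared across the leafplp modules."""


class LeafPLPError(Exception):
    """Base class for all leafplp errors."""


class InvalidArgumentError(LeafPLPError, ValueError):
    """An argument violates a documented precondition."""


class UnknownSpecError(LeafPLPError, KeyError):
    """Requested cultivar spec is not registered."""


class CanvasOverflowError(LeafPLPError, ValueError):
    """Requested blade does not fit on the requested canvas."""


class SegmentationEmptyError(LeafPLPError, ValueError):
    """Thresholding produced no foreground pixels."""


class UndefinedMomentError(LeafPLPError, ValueError):
    """Shape moments are undefined (degenerate mask)."""


class DegenerateCalibrationError(LeafPLPError, ValueError):
    """Turgid and dry reference masses do not bracket a water range."""


class UndefinedBaselineError(LeafPLPError, ZeroDivisionError):
    """Percent change from a zero baseline is undefined."""


class InconsistentLibraryError(LeafPLPError, ValueError):
    """Curve/feature blocks of a training library disagree in shape."""


class DivergenceError(LeafPLPError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, slave: str = ""):
        self.epoch = epoch
        self.slave = slave
        super().__init__(f"non-finite loss at epoch {epoch}" + (f" ({slave} slave)" if slave else ""))


class NotFittedError(LeafPLPError, RuntimeError):
    """Generator used before training."""


class UnderdeterminedFitError(LeafPLPError, ValueError):
    """Polynomial degree is too high for the number of curve points."""


class LeakageError(LeafPLPError, ValueError):
    """Test library shares leaf ids with the training library."""
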