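"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


class FormatError(ValueError):
    """Malformed input file (bad header, ragged rows, non-numeric cells)."""


class CalibrationError(RuntimeError):
    """Perplexity calibration failed to converge for some sample."""

    def __init__(self, row: int, residual: float):
        self.row = row
        self.residual = residual
        super().__init__(
            f"perplexity calibration did not converge for sample row {row} "
            f"(|2^H - perplexity| = {residual:.3g}); the point may duplicate "
            f"another sample exactly"
        )


class OptimizationDivergedError(RuntimeError):
    """The embedding left the trust region (|y| > 1e8)."""

    def __init__(self, iteration: int):
        self.iteration = iteration
        super().__init__(f"t-SNE optimization diverged at iteration {iteration}")


class ContractViolation(RuntimeError):
    """Internal shape/iteration bookkeeping mismatch."""
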