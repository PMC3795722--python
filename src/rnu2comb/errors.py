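"""Exception hierarchy for the rnu2comb pipeline."""


class Rnu2CombError(Exception):
    """Base class for all package errors."""


class ConfigError(Rnu2CombError):
    """Invalid simulation or analysis configuration."""


class InvalidAlleleError(Rnu2CombError):
    """Repeat-unit copy number outside the valid domain (n >= 1)."""


class GatingError(Rnu2CombError):
    """Repeat counting requested on a fibre that fails the flank-integrity gate."""


class CalibrationError(Rnu2CombError):
    """Per-fibre stretch calibration unavailable (motif not fully matched)."""


class AmbiguousPlacementError(Rnu2CombError):
    """Conflicting junction anchors: two disjoint candidate array intervals."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "conflicting junction-anchored candidates: "
            + ", ".join(f"{c[0]}-{c[1]}" for c in self.candidates)
        )


class CycleError(Rnu2CombError):
    """Cyclic contig overlap graph (unreachable from interval evidence)."""


class NoCallError(Rnu2CombError):
    """Too few supporting fibre counts to call a genotype."""
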