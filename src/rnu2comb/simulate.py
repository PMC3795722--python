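"""Synthetic combed-DNA fibre generator.

Emulates the statistical structure of fibre-FISH on molecularly combed DNA:
diploid genotypes drawn from the published allele spectrum, random fibre
breakage (truncated-normal fibre lengths), a per-fibre stretching factor near
the combing constant of 2 kb/µm, independent additive jitter on every signal
boundary, per-signal dropout, Poisson spurious signals, random fibre
orientation, and the cross-reacting RNU2-4P signal.  Ground truth (haplotype,
window, stretch, orientation, genotypes) is kept on a separate channel so the
analysis path never sees it.

Reproducibility contract: identical ``(config, seed)`` give byte-identical
output.  A counter-based RNG substream (``[seed, 1, individual, fibre]``) is
derived per fibre so cohorts can be regenerated or parallelised stably.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError
from .locus import Haplotype, LocusMap, build_haplotype, default_locus_map, \
    expected_signal_layout

# Allele spectrum of the 46 unrelated chromosomes (repeat units -> occurrences).
PUBLISHED_OCCURRENCES = {
    6: 1, 8: 1, 9: 1, 11: 2, 12: 1, 13: 1, 14: 2, 15: 1, 16: 1, 17: 1,
    18: 3, 19: 5, 20: 1, 21: 2, 22: 2, 23: 1, 25: 1, 27: 2, 28: 2, 29: 2,
    30: 1, 32: 2, 34: 2, 35: 2, 36: 1, 37: 2, 47: 2, 82: 1,
}
PUBLISHED_CHROMOSOMES = sum(PUBLISHED_OCCURRENCES.values())  # 46
PUBLISHED_FREQUENCIES = {k: v / PUBLISHED_CHROMOSOMES
                      for k, v in PUBLISHED_OCCURRENCES.items()}

_CHANNEL = {"red": "R", "green": "G", "blue": "B"}
_COLOR = {v: k for k, v in _CHANNEL.items()}


@dataclass
class Signal:
    """One coloured linear signal on a fibre, in µm from the fibre start."""

    channel: str                 # R / G / B
    start_um: float
    end_um: float
    truth_source: Optional[str] = None   # element id, "unit[i]" or "noise"


@dataclass
class FibreTruth:
    haplotype: str
    allele_n: int
    window_bp: tuple[int, int]
    stretch_kb_per_um: float
    orientation: str             # '+' or '-'


@dataclass
class Fibre:
    """One combed molecule: an ordered list of coloured signals."""

    fibre_id: str
    individual_id: str
    signals: list[Signal]
    truth: Optional[FibreTruth] = None

    @property
    def length_um(self) -> float:
        return max((s.end_um for s in self.signals), default=0.0)


@dataclass
class CohortConfig:
    """Study conditions for a simulated cohort.

    Defaults are the conditions of the genotyping study being emulated:
    2 kb/µm combing stretch, the published 46-chromosome allele spectrum,
    ~400 kb fibres.  Noise rates without a published value (dropout, spurious
    signals, jitter) are declared, tunable parameters.
    """

    n_individuals: int = 41
    genotypes: Optional[Sequence[tuple[int, int]]] = None
    allele_frequencies: Optional[dict] = None     # default: published allele spectrum
    fibres_per_individual: int = 15
    fibre_length_mean_kb: float = 400.0
    fibre_length_sd_kb: float = 80.0
    stretch_mean: float = 2.0                     # kb/µm
    stretch_sd: float = 0.05
    boundary_jitter_sd_kb: float = 0.3
    dropout_prob: float = 0.02
    false_signal_rate: float = 0.1                # Poisson mean per fibre
    orientation_prob: float = 0.5
    min_intact_per_haplotype: Optional[int] = None
    unrelated: Optional[Sequence[tuple[bool, bool]]] = None
    seed: int = 0

    def validate(self) -> None:
        for p in (self.dropout_prob, self.orientation_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability out of [0,1]: {p}")
        for s in (self.fibre_length_sd_kb, self.stretch_sd,
                  self.boundary_jitter_sd_kb, self.false_signal_rate):
            if s < 0:
                raise ConfigError(f"rate/sd must be >= 0: {s}")
        if self.stretch_mean <= 0 or self.fibre_length_mean_kb <= 0:
            raise ConfigError("stretch and fibre length means must be > 0")
        if self.n_individuals < 1:
            raise ConfigError("need at least one individual")
        if self.genotypes is not None:
            if len(self.genotypes) != self.n_individuals:
                raise ConfigError("explicit genotypes must cover every individual")
            for a, b in self.genotypes:
                if min(a, b) < 1:
                    raise ConfigError(f"invalid allele pair ({a},{b})")
        else:
            freqs = self.allele_frequencies or PUBLISHED_FREQUENCIES
            total = float(sum(freqs.values()))
            if not math.isclose(total, 1.0, abs_tol=0.01):
                raise ConfigError(f"allele frequencies sum to {total:.4f}, not ~1")
        if self.unrelated is not None and len(self.unrelated) != self.n_individuals:
            raise ConfigError("unrelated flags must cover every individual")


@dataclass
class CohortDataset:
    config: CohortConfig
    fibres: list[Fibre]
    genotypes: list[tuple[int, int]]
    unrelated: list[tuple[bool, bool]]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      nsd: float = 3.0, lower: Optional[float] = None) -> float:
    """Normal truncated at ±nsd; optionally conditioned on >= lower."""
    if sd == 0:
        if lower is not None and mean < lower:
            raise ConfigError(
                f"degenerate distribution at {mean} cannot reach {lower}")
        return mean
    if lower is not None and lower > mean + nsd * sd:
        raise ConfigError(
            f"required minimum {lower:.0f} exceeds distribution ceiling "
            f"{mean + nsd * sd:.0f}; increase the fibre length mean")
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= nsd * sd and (lower is None or x >= lower):
            return x
    raise ConfigError("truncated-normal rejection sampling failed")


def sample_genotypes(config: CohortConfig,
                     rng: np.random.Generator) -> list[tuple[int, int]]:
    """Two alleles per individual: passthrough of explicit genotypes or
    independent draws from the allele-frequency table."""
    config.validate()
    if config.genotypes is not None:
        return [tuple(g) for g in config.genotypes]
    freqs = config.allele_frequencies or PUBLISHED_FREQUENCIES
    values = np.array(sorted(freqs), dtype=int)
    p = np.array([freqs[v] for v in values], dtype=float)
    p = p / p.sum()
    draws = rng.choice(values, size=2 * config.n_individuals, p=p)
    return [(int(draws[2 * i]), int(draws[2 * i + 1]))
            for i in range(config.n_individuals)]


def _sample_window(rng, total_span, length_bp, require=None):
    if require is not None:
        r0, r1 = require
        lo = max(0.0, r1 - length_bp)
        hi = max(lo, min(r0, total_span - length_bp))
        start = rng.uniform(lo, hi) if hi > lo else lo
        return (start, min(start + length_bp, total_span))
    for _ in range(200):
        start = rng.uniform(-length_bp, total_span)
        w0, w1 = max(0.0, start), min(total_span, start + length_bp)
        if w1 - w0 >= min(20_000, total_span):
            return (w0, w1)
    return (0.0, min(length_bp, total_span))


def simulate_fibre(hap: Haplotype, config: CohortConfig,
                   rng: np.random.Generator, fibre_id: str = "f0",
                   individual_id: str = "I000",
                   require_region: Optional[object] = None,
                   haplotype_label: Optional[str] = None) -> Fibre:
    """Simulate one combed fibre from a haplotype.

    ``require_region`` conditions the breakage window on covering a named
    region of the haplotype ("flanks", "calibration", "full") or an explicit
    bp interval; the fibre length is then drawn from the same truncated
    normal conditioned on being long enough.
    """
    region = hap.regions.get(require_region, require_region) \
        if isinstance(require_region, str) else require_region
    min_len = None if region is None else (region[1] - region[0])

    stretch = _truncated_normal(rng, config.stretch_mean, config.stretch_sd)
    length_bp = 1_000.0 * _truncated_normal(
        rng, config.fibre_length_mean_kb, config.fibre_length_sd_kb,
        lower=None if min_len is None else min_len / 1_000.0)
    w0, w1 = _sample_window(rng, hap.total_span, length_bp, region)
    window_um = (w1 - w0) / (1_000.0 * stretch)
    jitter_bp = config.boundary_jitter_sd_kb * 1_000.0

    signals: list[Signal] = []
    for color, (s, e), src in expected_signal_layout(hap, (w0, w1)):
        if config.dropout_prob and rng.random() < config.dropout_prob:
            continue
        if jitter_bp:
            s = s + rng.normal(0.0, jitter_bp)
            e = e + rng.normal(0.0, jitter_bp)
        if e <= s:
            s, e = min(s, e), min(s, e) + 10.0
        s, e = max(s, w0), min(e, w1)
        if e - s < 1.0:
            continue
        signals.append(Signal(_CHANNEL[color],
                              (s - w0) / (1_000.0 * stretch),
                              (e - w0) / (1_000.0 * stretch), src))

    n_false = rng.poisson(config.false_signal_rate) if config.false_signal_rate else 0
    for _ in range(n_false):
        channel = ("R", "G", "B")[rng.integers(0, 3)]
        length_um = rng.uniform(0.5, 3.0) / stretch
        start = rng.uniform(0.0, max(window_um - length_um, 1e-6))
        signals.append(Signal(channel, start,
                              min(start + length_um, window_um), "noise"))

    orientation = "+"
    if rng.random() < config.orientation_prob:
        orientation = "-"
        signals = [Signal(s.channel, window_um - s.end_um,
                          window_um - s.start_um, s.truth_source)
                   for s in signals]
    signals.sort(key=lambda s: (s.start_um, s.end_um))

    truth = FibreTruth(haplotype_label or f"{individual_id}.h?",
                       hap.allele_n, (int(round(w0)), int(round(w1))),
                       stretch, orientation)
    return Fibre(fibre_id, individual_id, signals, truth)


def _covers_flanks(fibre: Fibre, hap: Haplotype) -> bool:
    w0, w1 = fibre.truth.window_bp
    r0, r1 = hap.regions["flanks"]
    return w0 <= r0 and w1 >= r1


def simulate_cohort(config: CohortConfig,
                    lmap: Optional[LocusMap] = None) -> CohortDataset:
    """Simulate a whole cohort; deterministic for a given ``(config, seed)``.

    When ``min_intact_per_haplotype`` is set, base fibres are topped up with
    window-conditioned fibres until each haplotype has that many fibres whose
    window spans the full flank-to-flank region (mirroring the selection of
    analysable fibres at the microscope).
    """
    config.validate()
    lmap = lmap or default_locus_map()
    rng_geno = np.random.default_rng([config.seed, 0])
    genotypes = sample_genotypes(config, rng_geno)
    unrelated = list(config.unrelated) if config.unrelated is not None \
        else [(True, True)] * config.n_individuals

    hap_cache: dict[int, Haplotype] = {}

    def hap_for(n: int) -> Haplotype:
        if n not in hap_cache:
            hap_cache[n] = build_haplotype(lmap, n)
        return hap_cache[n]

    fibres: list[Fibre] = []
    for i, (a1, a2) in enumerate(genotypes):
        ind = f"I{i:03d}"
        haps = (hap_for(a1), hap_for(a2))
        intact = [0, 0]
        k = 0
        for _ in range(config.fibres_per_individual):
            rng = np.random.default_rng([config.seed, 1, i, k])
            h = int(rng.integers(0, 2))
            fib = simulate_fibre(haps[h], config, rng, f"{ind}:{k}", ind,
                                 haplotype_label=f"{ind}.h{h + 1}")
            if _covers_flanks(fib, haps[h]):
                intact[h] += 1
            fibres.append(fib)
            k += 1
        quota = config.min_intact_per_haplotype
        if quota:
            for h in (0, 1):
                guard = 0
                while intact[h] < quota:
                    guard += 1
                    if guard > 100 * quota:
                        raise ConfigError(
                            f"cannot reach {quota} intact fibres for {ind}.h{h + 1}")
                    rng = np.random.default_rng([config.seed, 1, i, k])
                    fib = simulate_fibre(haps[h], config, rng, f"{ind}:{k}",
                                         ind, require_region="flanks",
                                         haplotype_label=f"{ind}.h{h + 1}")
                    if _covers_flanks(fib, haps[h]):
                        intact[h] += 1
                    fibres.append(fib)
                    k += 1
    return CohortDataset(config, fibres, genotypes, unrelated)


def reverse_fibre(fibre: Fibre) -> Fibre:
    """Mirror a fibre's signal coordinates (orientation symmetry helper)."""
    m = fibre.length_um
    signals = [Signal(s.channel, m - s.end_um, m - s.start_um, s.truth_source)
               for s in fibre.signals]
    signals.sort(key=lambda s: (s.start_um, s.end_um))
    return replace(fibre, signals=signals)


# --- the published-cohort preset -------------------------------------------

def published_cohort_pairing() -> tuple[list[tuple[int, int]], list[tuple[bool, bool]]]:
    """Deterministic 41-individual construction of the published cohort.

    The 46 unrelated chromosomes carry exactly the published allele multiset:
    one homozygote (19,19) plus 22 heterozygous pairs formed by pairing the
    sorted lower half of the remaining 44 alleles with the sorted upper half
    (every pair differs by >= 2 copies).  18 further "related" individuals
    duplicate the first 18 unrelated genotypes (identity-by-descent fill-in);
    their chromosomes are flagged as excluded from unrelated-chromosome
    accounting.  40 of 41 individuals are heterozygous.
    """
    multiset: list[int] = []
    for allele, occ in sorted(PUBLISHED_OCCURRENCES.items()):
        multiset.extend([allele] * occ)
    multiset.remove(19)
    multiset.remove(19)
    multiset.sort()
    half = len(multiset) // 2
    pairs = [(19, 19)] + list(zip(multiset[:half], multiset[half:]))
    related = [pairs[1 + (j % 18)] for j in range(18)]
    genotypes = pairs + related
    unrelated = [(True, True)] * len(pairs) + [(False, False)] * len(related)
    return genotypes, unrelated


def published_cohort_config(seed: int, fibres_per_individual: int = 15,
                         min_intact_per_haplotype: int = 10,
                         **overrides) -> CohortConfig:
    """Cohort config reproducing the published study conditions."""
    genotypes, unrelated = published_cohort_pairing()
    return CohortConfig(
        n_individuals=len(genotypes), genotypes=genotypes,
        unrelated=unrelated, fibres_per_individual=fibres_per_individual,
        min_intact_per_haplotype=min_intact_per_haplotype, seed=seed,
        **overrides)


def zero_noise(config: CohortConfig) -> CohortConfig:
    """A copy of ``config`` with every noise source switched off."""
    return replace(config, stretch_sd=0.0, boundary_jitter_sd_kb=0.0,
                   dropout_prob=0.0, false_signal_rate=0.0)
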