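"""Physical model of the 17q21 RNU2 region.

The RNU2 macrosatellite is a tandem array of a 6,132-bp repeat unit sitting
~124 kb telomeric to BRCA1 on chromosome 17.  Fibre-FISH on combed DNA reads
the locus as an ordered "Genomic Morse Code" (GMC): 17 multi-colour probe
signals over ~200 kb of the BRCA1 region, two flanking probe pairs
(FP1/FP2 centromeric, FP3/FP4 telomeric of the array), one red signal per
repeat unit, and a cross-reacting red signal at the RNU2-4P pseudogene
further telomeric.

This module holds that map in a self-contained linear frame (0-based,
half-open bp) anchored so that the array start equals the Build-37
coordinate 41,399,577 — printed assembly coordinates can be used literally —
and expands diploid alleles into haplotype coordinate maps from which
expected signal layouts are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

from .errors import ConfigError, InvalidAlleleError

# --- repeat unit -----------------------------------------------------------
UNIT_LENGTH = 6_132           # bp, sequenced repeat-unit length
L4_BP = 434                   # PCR fragment sizes of the two unit probes
L5_BP = 1_959
LABEL_OFFSET = 1_000          # declared offset of the labeled span in the unit
LABEL_SPAN = L4_BP + L5_BP    # 2,393 bp contiguous red span per unit

# --- reference frame -------------------------------------------------------
ARRAY_START = 41_399_577                       # Build-37 array start
ASSEMBLY_ARRAY_INTERVAL = (41_399_577, 41_401_198)  # partial unit in assembly
FLANK_GAP_CENTROMERIC = 7_300                  # FP2 end -> array start
FLANK_GAP_TELOMERIC = 2_000                    # array end -> FP3 start
BRCA1_END_TO_ARRAY_BP = 123_700                # expected from the assembly
ARRAY_TO_RNU2_4P_BP = 63_400                   # array end -> pseudogene
CALIBRATION_MOTIF_BP = 128_000                 # stretch-calibration motif
DEFAULT_STRETCH = 2.0                          # kb/µm, combing constant
RNU2_4P_BP = 289                               # pseudogene length

# --- GMC default table (versioned: v1) -------------------------------------
# Published schema: 17 elements, 1-3 bars each, green/red/blue, over 200 kb.
# Exact coordinates are packaged defaults (declared constants): elements sit
# on a 12-kb raster; two elements are pinned so that (a) the calibration
# motif, first GMC bar to the designated motif-end bar, is exactly 128 kb and
# (b) the BRCA1-end anchor bar sits exactly 123,700 bp centromeric of the
# array start.
GMC_START = 41_180_000
GMC_SPACING = 12_000
GMC_N = 17
BRCA1_ANCHOR_ELEMENT = "GMC08"
MOTIF_START_ELEMENT = "GMC01"
MOTIF_END_ELEMENT = "GMC11"

_GMC_COLORS = (
    "green", "blue", "red", "green", "blue", "green", "red", "blue",
    "green", "blue", "green", "red", "blue", "green", "blue", "green", "blue",
)
_GMC_NBARS = (2, 1, 3, 2, 1, 2, 3, 3, 1, 3, 2, 1, 2, 3, 1, 2, 2)
_STD_BAR_OFFSETS = ((0, 1_500), (2_500, 4_000), (5_000, 6_500))
# pinned bar layouts (offsets relative to the element raster position)
_GMC_CUSTOM_BARS = {
    # GMC08: last bar ends at ARRAY_START - 123,700 = 41,275,877
    7: ((0, 2_000), (4_000, 6_000), (9_877, 11_877)),
    # GMC11: last bar ends at GMC_START + 128,000 = 41,308,000
    10: ((0, 3_000), (5_000, 8_000)),
}

VALID_COLORS = ("red", "green", "blue")
VALID_ROLES = ("gmc", "flank_centromeric", "flank_telomeric", "array_probe",
               "pseudogene")


@dataclass(frozen=True)
class ProbeElement:
    """One barcode element: 1-3 co-coloured bars at fixed genomic positions."""

    id: str
    color: str
    bars: tuple[tuple[int, int], ...]
    role: str

    def __post_init__(self):
        if self.color not in VALID_COLORS:
            raise ConfigError(f"{self.id}: invalid color {self.color!r}")
        if self.role not in VALID_ROLES:
            raise ConfigError(f"{self.id}: invalid role {self.role!r}")
        if not 1 <= len(self.bars) <= 3:
            raise ConfigError(f"{self.id}: needs 1-3 bars")
        prev_end = -1
        for s, e in self.bars:
            if not (0 <= s < e):
                raise ConfigError(f"{self.id}: bad bar ({s}, {e})")
            if s < prev_end:
                raise ConfigError(f"{self.id}: bars overlap or unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.bars[0][0], self.bars[-1][1])


@dataclass(frozen=True)
class RepeatUnitModel:
    """The 6,132-bp unit with its labeled (red) sub-intervals.

    The two unit probes target close regions and appear as a single signal;
    by default they form one contiguous 2,393-bp labeled span starting at
    offset ``LABEL_OFFSET``.
    """

    unit_length: int = UNIT_LENGTH
    labeled_intervals: tuple[tuple[int, int], ...] = (
        (LABEL_OFFSET, LABEL_OFFSET + L4_BP),
        (LABEL_OFFSET + L4_BP, LABEL_OFFSET + LABEL_SPAN),
    )
    color: str = "red"

    def __post_init__(self):
        total = 0
        for s, e in self.labeled_intervals:
            if not (0 <= s < e <= self.unit_length):
                raise ConfigError(f"labeled interval ({s},{e}) outside unit")
            total += e - s
        if total >= self.unit_length:
            raise ConfigError("labeled span must be shorter than the unit")

    @property
    def label_start(self) -> int:
        return self.labeled_intervals[0][0]

    @property
    def label_end(self) -> int:
        return self.labeled_intervals[-1][1]

    @property
    def label_span(self) -> int:
        return self.label_end - self.label_start


@dataclass(frozen=True)
class LocusMap:
    """Ordered element map of the region plus the named map constants."""

    reference_name: str
    elements: tuple[ProbeElement, ...]
    array_anchor: tuple[int, int]
    unit: RepeatUnitModel
    flank_gap_centromeric: int = FLANK_GAP_CENTROMERIC
    flank_gap_telomeric: int = FLANK_GAP_TELOMERIC
    gmc_calibration_motif: tuple[int, int] = (GMC_START,
                                              GMC_START + CALIBRATION_MOTIF_BP)
    brca1_end_to_array_bp: int = BRCA1_END_TO_ARRAY_BP
    array_to_rnu2_4p_bp: int = ARRAY_TO_RNU2_4P_BP
    default_stretch: float = DEFAULT_STRETCH
    brca1_anchor_element: str = BRCA1_ANCHOR_ELEMENT
    motif_start_element: str = MOTIF_START_ELEMENT
    motif_end_element: str = MOTIF_END_ELEMENT

    def __post_init__(self):
        prev_end = -1
        for el in self.elements:
            s, e = el.span
            if s < prev_end:
                raise ConfigError(f"element {el.id} overlaps its predecessor")
            prev_end = e
        m0, m1 = self.gmc_calibration_motif
        if m1 - m0 != CALIBRATION_MOTIF_BP:
            raise ConfigError("calibration motif must span exactly 128,000 bp")
        a0, a1 = self.array_anchor
        for el in self.elements:
            cen = el.span[1] <= a0
            tel = el.span[0] >= a1
            if not (cen or tel):
                raise ConfigError(f"element {el.id} overlaps the array anchor")
            if el.role == "flank_centromeric" and not cen:
                raise ConfigError(f"{el.id} must be centromeric of the array")
            if el.role in ("flank_telomeric", "pseudogene") and not tel:
                raise ConfigError(f"{el.id} must be telomeric of the array")

    def element(self, element_id: str) -> ProbeElement:
        for el in self.elements:
            if el.id == element_id:
                return el
        raise KeyError(element_id)

    def centromeric_elements(self) -> tuple[ProbeElement, ...]:
        return tuple(e for e in self.elements if e.span[1] <= self.array_anchor[0])

    def telomeric_elements(self) -> tuple[ProbeElement, ...]:
        return tuple(e for e in self.elements if e.span[0] >= self.array_anchor[1])


def _default_elements() -> tuple[ProbeElement, ...]:
    elements = []
    for k in range(GMC_N):
        base = GMC_START + k * GMC_SPACING
        offsets = _GMC_CUSTOM_BARS.get(k, _STD_BAR_OFFSETS[: _GMC_NBARS[k]])
        bars = tuple((base + s, base + e) for s, e in offsets)
        elements.append(ProbeElement(f"GMC{k + 1:02d}", _GMC_COLORS[k], bars, "gmc"))

    fp2_end = ARRAY_START - FLANK_GAP_CENTROMERIC          # 41,392,277
    fp2_start = fp2_end - 4_860
    fp1_end = fp2_start - 1_000
    fp1_start = fp1_end - 4_393
    elements.append(ProbeElement(
        "FP1", "green",
        ((fp1_start, fp1_start + 1_800), (fp1_start + 2_600, fp1_end)),
        "flank_centromeric"))
    elements.append(ProbeElement(
        "FP2", "blue",
        ((fp2_start, fp2_start + 2_000), (fp2_start + 2_900, fp2_end)),
        "flank_centromeric"))

    anchor_end = ASSEMBLY_ARRAY_INTERVAL[1]
    fp3_start = anchor_end + FLANK_GAP_TELOMERIC           # 41,403,198
    fp3_end = fp3_start + 7_009
    elements.append(ProbeElement(
        "FP3", "green",
        ((fp3_start, fp3_start + 2_500), (fp3_start + 4_600, fp3_end)),
        "flank_telomeric"))
    fp4_start = fp3_end + 1_000
    elements.append(ProbeElement(
        "FP4", "blue",
        ((fp4_start, fp4_start + 1_900), (fp4_start + 3_200, fp4_start + 5_340)),
        "flank_telomeric"))

    p_start = anchor_end + ARRAY_TO_RNU2_4P_BP             # 41,464,598
    elements.append(ProbeElement(
        "RNU2-4P", "red", ((p_start, p_start + RNU2_4P_BP),), "pseudogene"))
    return tuple(elements)


@lru_cache(maxsize=1)
def default_locus_map() -> LocusMap:
    """The packaged default map (GMC coordinate table v1)."""
    return LocusMap(
        reference_name="chr17-model",
        elements=_default_elements(),
        array_anchor=ASSEMBLY_ARRAY_INTERVAL,
        unit=RepeatUnitModel(),
    )


# --- haplotype expansion ---------------------------------------------------

HEAD_MARGIN = 5_000   # unlabeled DNA flanking the mapped region on a haplotype
TAIL_MARGIN = 5_000

SourceBar = tuple[str, str, int, int]  # (source id, color, start, end) in bp


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's expanded coordinate map for a given allele."""

    allele_n: int
    bars: tuple[SourceBar, ...]
    element_layout: tuple[tuple[str, tuple[int, int]], ...]
    array_segment: tuple[int, int]
    total_span: int
    regions: dict = field(compare=False, default_factory=dict)


def build_haplotype(lmap: LocusMap, n: int) -> Haplotype:
    """Expand the locus map for an allele of ``n`` repeat units.

    Coordinates are haplotype-local (0-based at ``HEAD_MARGIN`` bp before the
    first mapped element); the array anchor interval is replaced by ``n``
    adjacent unit copies, shifting every telomeric element accordingly.
    """
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 1:
        raise InvalidAlleleError(f"allele copy number must be an integer >= 1, got {n!r}")
    a0, a1 = lmap.array_anchor
    anchor_len = a1 - a0
    origin = min(el.span[0] for el in lmap.elements) - HEAD_MARGIN
    shift_tel = n * lmap.unit.unit_length - anchor_len

    bars: list[SourceBar] = []
    layout: list[tuple[str, tuple[int, int]]] = []
    for el in lmap.elements:
        off = -origin if el.span[1] <= a0 else -origin + shift_tel
        for s, e in el.bars:
            bars.append((el.id, el.color, s + off, e + off))
        layout.append((el.id, (el.span[0] + off, el.span[1] + off)))

    unit = lmap.unit
    arr0 = a0 - origin
    for i in range(n):
        u0 = arr0 + i * unit.unit_length
        bars.append((f"unit[{i}]", unit.color,
                     u0 + unit.label_start, u0 + unit.label_end))
        layout.append((f"unit[{i}]", (u0, u0 + unit.unit_length)))
    array_segment = (arr0, arr0 + n * unit.unit_length)

    bars.sort(key=lambda b: b[2])
    layout.sort(key=lambda b: b[1][0])
    total_span = max(e for _, _, _, e in bars) + TAIL_MARGIN

    def span_of(eid: str) -> tuple[int, int]:
        el = lmap.element(eid)
        off = -origin if el.span[1] <= a0 else -origin + shift_tel
        return (el.span[0] + off, el.span[1] + off)

    fp1, fp4 = span_of("FP1"), span_of("FP4")
    gmc1 = span_of(lmap.motif_start_element)
    regions = {
        # flank-to-flank: a fibre covering this is eligible for counting
        "flanks": (fp1[0], fp4[1]),
        # calibration motif through the first unit label: distance fibres
        "calibration": (gmc1[0], arr0 + unit.unit_length),
        "full": (gmc1[0], span_of("RNU2-4P")[1]),
    }
    return Haplotype(
        allele_n=n,
        bars=tuple(bars),
        element_layout=tuple(layout),
        array_segment=array_segment,
        total_span=total_span,
        regions=regions,
    )


def expected_signal_layout(
    hap: Haplotype, window: tuple[float, float]
) -> list[tuple[str, tuple[float, float], str]]:
    """Labeled spans intersecting ``window``, clipped to it.

    Returns ``(color, (start, end), source id)`` ordered by start; an empty or
    inverted window yields an empty list.  Array-unit signals carry source ids
    ``unit[i]``; the cross-reacting pseudogene signal carries ``RNU2-4P``.
    """
    w0, w1 = window
    if w1 <= w0:
        return []
    out = []
    for src, color, s, e in hap.bars:
        cs, ce = max(s, w0), min(e, w1)
        if cs < ce:
            out.append((color, (cs, ce), src))
    return out
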