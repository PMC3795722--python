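"""Per-fibre inference on combed-DNA signal tables.

A fibre is an anonymous ordered list of coloured signals in µm.  Analysis
proceeds in four steps:

1. ``match_barcode`` — identify the fibre on the locus barcode.  The map's
   elements are split into a centromeric block (GMC + FP1/FP2) and a
   telomeric block (FP3/FP4 + RNU2-4P); the two blocks are separated by the
   tandem array, whose unknown length forbids a single affine fit across it.
   For each orientation and each block, offset hypotheses are seeded from
   colour-matched bar pairs at the nominal 2 kb/µm stretch, scored by greedy
   one-to-one assignment within a positional tolerance, and the best
   hypothesis is refined by iterated least squares (observed µm -> map kb).
   The orientation matching more bars wins.

2. ``calibrate_stretch`` — the designated 128-kb motif inside the barcode
   gives the fibre's exact stretching factor (128 / measured µm span).

3. ``count_repeats`` — only on fibres whose four flanking probes are all
   matched (integrity gate): red signals strictly between the inner FP2 and
   FP3 edges are merged (< merge_gap) and counted; units hidden by signal
   dropout are imputed from gap lengths, a missing unit widening a gap by
   one 6.132-kb period.

4. ``measure_distances`` — calibrated distances: BRCA1 end to array start,
   per-signal lengths and inter-signal gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import CalibrationError, GatingError
from .locus import LABEL_OFFSET, LocusMap, default_locus_map
from .simulate import Fibre

logger = logging.getLogger(__name__)

UNIT_KB = 6.132
LABEL_KB = 2.393
DARK_INTERNAL_KB = UNIT_KB - LABEL_KB          # 3.739 kb between unit signals

_CHANNEL_FROM_COLOR = {"red": "R", "green": "G", "blue": "B"}


@dataclass
class BlockFit:
    """Affine map (oriented observed µm) -> (reference kb) for one block."""

    scale: float                                # kb per µm (~ stretch)
    offset: float
    pairs: dict = field(default_factory=dict)   # (elem, bar_idx) -> sig index


@dataclass
class FibreCall:
    """Everything inferred from a single fibre."""

    fibre_id: str
    individual_id: str = ""
    orientation: str = "unknown"                # '+', '-', 'unknown'
    matched_elements: dict = field(default_factory=dict)  # id -> [sig idx]
    stretch_estimate: Optional[float] = None    # kb/µm, motif-calibrated
    integrity: str = "none"   # full | centromeric_only | telomeric_only | none
    repeat_count: Optional[int] = None
    distances: dict = field(default_factory=dict)
    status: str = "unusable"  # countable | measurable_only | unusable
    # internal state used by downstream steps
    matched_bars: dict = field(default_factory=dict, repr=False)
    blocks: dict = field(default_factory=dict, repr=False)
    mirror_um: float = field(default=0.0, repr=False)
    mirrored: bool = field(default=False, repr=False)

    def measurement_stretch(self, nominal: float = 2.0) -> float:
        """Best available kb/µm factor: calibrated, else barcode-fit, else nominal."""
        if self.stretch_estimate:
            return self.stretch_estimate
        scales = [b.scale for b in self.blocks.values() if b is not None]
        return float(np.mean(scales)) if scales else nominal


def _expected_blocks(lmap: LocusMap):
    """Expected bars per block, split into a fit set and a post-hoc set.

    Returns ``(fit, posthoc)`` dicts keyed by block ("C"/"T") of
    ``(elem, bar_idx, channel, center_kb, start_kb, end_kb)`` tuples.  Red
    bars (red GMC elements and the cross-reacting pseudogene) are excluded
    from fitting: under a loose tolerance a red probe bar finds an array
    signal (one every ~6 kb) almost anywhere, so red matches would reward
    wrong placements and distort the scale fit.  They are assigned post hoc
    from the green/blue-anchored transform instead.
    """
    fit = {"C": [], "T": []}
    posthoc = {"C": [], "T": []}
    for el in lmap.elements:
        key = "C" if el.span[1] <= lmap.array_anchor[0] else "T"
        ch = _CHANNEL_FROM_COLOR[el.color]
        dest = posthoc if ch == "R" else fit
        for bi, (s, e) in enumerate(el.bars):
            dest[key].append((el.id, bi, ch,
                              (s + e) / 2_000.0, s / 1_000.0, e / 1_000.0))
    return fit, posthoc


def _assign(obs_by_ch, exp_bars, scale, offset, tol_kb):
    """Greedy one-to-one assignment of expected bars to observed signals.

    Returns ``(pairs, total_error_kb)``; pairs are ``(exp idx, channel,
    per-channel obs idx)``, assigned smallest-error first.
    """
    cands = []
    for k, (eid, bi, ch, c_kb, _, _) in enumerate(exp_bars):
        centers, idxs = obs_by_ch.get(ch, (None, None))
        if centers is None or len(centers) == 0:
            continue
        pred_um = (c_kb - offset) / scale
        j = int(np.searchsorted(centers, pred_um))
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < len(centers):
                err = abs(scale * centers[jj] + offset - c_kb)
                if err <= tol_kb:
                    cands.append((err, k, jj, ch))
    cands.sort()
    used_exp, used_obs, pairs = set(), set(), []
    total = 0.0
    for err, k, jj, ch in cands:
        if k in used_exp or (ch, jj) in used_obs:
            continue
        used_exp.add(k)
        used_obs.add((ch, jj))
        pairs.append((k, ch, jj))
        total += err
    return pairs, total


def _fit_block(obs_by_ch, exp_bars, nominal, tol_kb):
    """Best affine fit of one expected block onto the oriented signals.

    Hypotheses rank by (matched bars, smallest total error); the refined
    scale must stay inside the physically plausible combing-stretch band
    around the nominal 2 kb/µm.
    """
    # Offset hypotheses from colour-matched (green/blue) bar pairs at the
    # nominal stretch, deduplicated on a 2-kb grid.
    hyp = []
    for k, (eid, bi, ch, c_kb, _, _) in enumerate(exp_bars):
        centers, _ = obs_by_ch.get(ch, (None, None))
        if centers is None:
            continue
        for x in centers:
            hyp.append(c_kb - nominal * x)
    if not hyp:
        return None
    scale_lo, scale_hi = 0.7 * nominal, 1.35 * nominal
    offsets = sorted({round(h / 2.0) * 2.0 for h in hyp})
    scored = []
    for off in offsets:
        pairs, err = _assign(obs_by_ch, exp_bars, nominal, off, tol_kb)
        if len(pairs) >= 2:
            scored.append(((len(pairs), -err), off, pairs))
    if not scored:
        return None
    scored.sort(key=lambda t: t[0], reverse=True)

    def refine(off, pairs):
        scale, offset, err = nominal, off, None
        for _ in range(4):
            xs = [obs_by_ch[ch][0][jj] for _, ch, jj in pairs]
            ys = [exp_bars[k][3] for k, _, _ in pairs]
            if len(xs) >= 2 and max(xs) - min(xs) > 1e-6:
                a, b = np.polyfit(xs, ys, 1)
                if scale_lo <= a <= scale_hi:
                    scale, offset = float(a), float(b)
            new_pairs, err = _assign(obs_by_ch, exp_bars, scale, offset, tol_kb)
            if set(new_pairs) == set(pairs):
                pairs = new_pairs
                break
            if len(new_pairs) >= len(pairs):
                pairs = new_pairs
        _, err = _assign(obs_by_ch, exp_bars, scale, offset, tol_kb)
        return (len(pairs), -err), scale, offset, pairs

    best = None
    for _, off, pairs in scored[:5]:
        cand = refine(off, pairs)
        if best is None or cand[0] > best[0]:
            best = cand
    (_, _), scale, offset, best_pairs = best[0], best[1], best[2], best[3]
    if len(best_pairs) < 2:
        return None
    fit = BlockFit(scale=scale, offset=offset)
    for k, ch, jj in best_pairs:
        eid, bi = exp_bars[k][0], exp_bars[k][1]
        fit.pairs[(eid, bi)] = (ch, jj)
    return fit


def _oriented(fibre: Fibre, mirrored: bool):
    """Per-channel sorted signal centers in the oriented frame."""
    m = fibre.length_um
    obs = {}
    raw = {}
    for i, s in enumerate(fibre.signals):
        c = (s.start_um + s.end_um) / 2.0
        iv = (s.start_um, s.end_um)
        if mirrored:
            c = m - c
            iv = (m - s.end_um, m - s.start_um)
        obs.setdefault(s.channel, []).append((c, i, iv))
    out = {}
    for ch, rows in obs.items():
        rows.sort()
        out[ch] = (np.array([r[0] for r in rows]), [r[1] for r in rows])
        raw[ch] = {j: rows[j][2] for j in range(len(rows))}
    return out, raw, m


def match_barcode(fibre: Fibre, lmap: Optional[LocusMap] = None,
                  tol_kb: float = 5.0, min_elements: int = 4) -> FibreCall:
    """Identify a fibre on the barcode, trying both orientations."""
    lmap = lmap or default_locus_map()
    call = FibreCall(fibre_id=fibre.fibre_id, individual_id=fibre.individual_id)
    if not fibre.signals:
        return call
    exp_blocks, posthoc_blocks = _expected_blocks(lmap)
    nominal = lmap.default_stretch

    results = {}
    for mirrored in (False, True):
        obs, raw, m = _oriented(fibre, mirrored)
        fits = {key: _fit_block(obs, bars, nominal, tol_kb)
                for key, bars in exp_blocks.items()}
        n = sum(len(f.pairs) for f in fits.values() if f is not None)
        results[mirrored] = (n, fits, obs, raw, m)

    n_plus, n_minus = results[False][0], results[True][0]
    if n_plus == 0 and n_minus == 0:
        return call
    if n_plus == n_minus:
        mirrored, call.orientation = False, "unknown"
    elif n_plus > n_minus:
        mirrored, call.orientation = False, "+"
    else:
        mirrored, call.orientation = True, "-"
    _, fits, obs, raw, m = results[mirrored]
    call.mirrored, call.mirror_um = mirrored, m
    call.blocks = {k: v for k, v in fits.items() if v is not None}

    # Resolve cross-block claims on the same observed signal: the blocks are
    # physically disjoint, so a conflict means one fit is wrong — keep the
    # claim from the block with more matches.
    if len(call.blocks) == 2:
        sizes = {k: len(f.pairs) for k, f in call.blocks.items()}
        major = max(sizes, key=sizes.get)
        claimed = {v for v in call.blocks[major].pairs.values()}
        minor = "T" if major == "C" else "C"
        call.blocks[minor].pairs = {
            kk: vv for kk, vv in call.blocks[minor].pairs.items()
            if vv not in claimed}
        if len(call.blocks[minor].pairs) < 2:
            del call.blocks[minor]

    for key, fit in call.blocks.items():
        for (eid, bi), (ch, jj) in fit.pairs.items():
            sig_idx = obs[ch][1][jj]
            call.matched_elements.setdefault(eid, []).append(sig_idx)
            call.matched_bars[(eid, bi)] = (raw[ch][jj], sig_idx)

    # Post-hoc assignment of red barcode bars from the fitted transforms,
    # under a tighter tolerance: red barcode bars all lie far from the
    # array, so a correct fit predicts them nowhere near array signals.
    used = {(ch, jj) for f in call.blocks.values()
            for (ch, jj) in f.pairs.values()}
    red_tol = min(tol_kb, 3.0)
    for key, bars in posthoc_blocks.items():
        bfit = call.blocks.get(key)
        if bfit is None:
            continue
        centers, _ = obs.get("R", (None, None))
        if centers is None or len(centers) == 0:
            continue
        for eid, bi, ch, c_kb, _, _ in bars:
            errs = np.abs(bfit.scale * centers + bfit.offset - c_kb)
            order = np.argsort(errs)
            for jj in order[:3]:
                jj = int(jj)
                if errs[jj] > red_tol:
                    break
                if (ch, jj) in used:
                    continue
                used.add((ch, jj))
                sig_idx = obs[ch][1][jj]
                call.matched_elements.setdefault(eid, []).append(sig_idx)
                call.matched_bars[(eid, bi)] = (raw[ch][jj], sig_idx)
                break

    cen = all(e in call.matched_elements for e in ("FP1", "FP2"))
    tel = all(e in call.matched_elements for e in ("FP3", "FP4"))
    call.integrity = ("full" if cen and tel else
                      "centromeric_only" if cen else
                      "telomeric_only" if tel else "none")
    n_el = len(call.matched_elements)
    call.status = ("countable" if call.integrity == "full" else
                   "measurable_only" if n_el >= min_elements else "unusable")
    return call


def _bar_edge(call: FibreCall, lmap: LocusMap, elem_id: str,
              stretch: float, side: str) -> Optional[float]:
    """Oriented µm position of an element's inner (array-facing) edge.

    If the innermost bar dropped out, the edge is extrapolated from any
    matched bar using the known intra-element bp offsets.
    """
    el = lmap.element(elem_id)
    target_bp = el.span[1] if side == "tel" else el.span[0]
    best = None
    for bi, (s, e) in enumerate(el.bars):
        hit = call.matched_bars.get((elem_id, bi))
        if hit is None:
            continue
        (os_um, oe_um), _ = hit
        if side == "tel":
            pos = oe_um + (target_bp - e) / (1_000.0 * stretch)
        else:
            pos = os_um - (s - target_bp) / (1_000.0 * stretch)
        extrapolated = abs(target_bp - (e if side == "tel" else s))
        if best is None or extrapolated < best[0]:
            best = (extrapolated, pos)
    return None if best is None else best[1]


def _array_red_signals(call: FibreCall, fibre: Fibre, lmap: LocusMap,
                       stretch: float):
    """Oriented red intervals strictly between the inner FP2/FP3 edges."""
    lo = _bar_edge(call, lmap, "FP2", stretch, "tel")
    hi = _bar_edge(call, lmap, "FP3", stretch, "cen")
    if lo is None or hi is None:
        return None, None, []
    assigned = {i for idxs in call.matched_elements.values() for i in idxs}
    m = call.mirror_um
    reds = []
    for i, s in enumerate(fibre.signals):
        if s.channel != "R" or i in assigned:
            continue
        iv = (m - s.end_um, m - s.start_um) if call.mirrored \
            else (s.start_um, s.end_um)
        c = (iv[0] + iv[1]) / 2.0
        if lo < c < hi:
            reds.append(iv)
    reds.sort()
    return lo, hi, reds


def _merge(intervals, max_gap_um):
    merged = []
    for s, e in intervals:
        if merged and s - merged[-1][1] < max_gap_um:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return merged


def count_repeats(call: FibreCall, fibre: Fibre,
                  lmap: Optional[LocusMap] = None,
                  merge_gap_kb: float = 1.0) -> int:
    """Repeat-unit count between the flanking probes.

    Requires full flank integrity.  Adjacent red detections closer than
    ``merge_gap_kb`` merge into one signal.  Units whose signal dropped out
    are imputed from gap lengths: each missing unit widens a dark gap by one
    6.132-kb period (leading gap baseline 8.3 kb, internal 3.739 kb,
    trailing 4.739 kb).  The RNU2-4P cross-reaction lies outside the flanks
    and is never counted.
    """
    lmap = lmap or default_locus_map()
    if call.integrity != "full":
        raise GatingError(
            f"{call.fibre_id}: repeat counting requires full flank integrity "
            f"(got {call.integrity})")
    stretch = call.measurement_stretch(lmap.default_stretch)
    lo, hi, reds = _array_red_signals(call, fibre, lmap, stretch)
    if lo is None or hi is None or hi <= lo:
        raise GatingError(
            f"{call.fibre_id}: inconsistent flank geometry on the fibre")
    merged = _merge(reds, merge_gap_kb / stretch)

    lead_dark = (lmap.flank_gap_centromeric + lmap.unit.label_start) / 1_000.0
    trail_dark = ((lmap.unit.unit_length - lmap.unit.label_end)
                  + lmap.flank_gap_telomeric) / 1_000.0
    internal_dark = (lmap.unit.unit_length - lmap.unit.label_span) / 1_000.0
    unit_kb = lmap.unit.unit_length / 1_000.0

    def hidden(gap_kb: float, baseline: float) -> int:
        return max(0, int(np.floor((gap_kb - baseline) / unit_kb + 0.5)))

    if not merged:
        span_kb = (hi - lo) * stretch
        count = max(0, int(np.floor(
            (span_kb - (lmap.flank_gap_centromeric
                        + lmap.flank_gap_telomeric) / 1_000.0) / unit_kb + 0.5)))
    else:
        count = len(merged)
        count += hidden((merged[0][0] - lo) * stretch, lead_dark)
        count += hidden((hi - merged[-1][1]) * stretch, trail_dark)
        for (s0, e0), (s1, e1) in zip(merged, merged[1:]):
            count += hidden((s1 - e0) * stretch, internal_dark)
    call.repeat_count = count
    return count


def calibrate_stretch(call: FibreCall,
                      lmap: Optional[LocusMap] = None) -> float:
    """Per-fibre stretching factor from the 128-kb calibration motif.

    Both motif endpoints (the first bar of the motif-start element and the
    last bar of the motif-end element) must be matched on the fibre.
    """
    lmap = lmap or default_locus_map()
    start_el = lmap.element(lmap.motif_start_element)
    end_el = lmap.element(lmap.motif_end_element)
    lo = call.matched_bars.get((start_el.id, 0))
    hi = call.matched_bars.get((end_el.id, len(end_el.bars) - 1))
    if lo is None or hi is None:
        raise CalibrationError(
            f"{call.fibre_id}: calibration motif not fully matched")
    measured_um = hi[0][1] - lo[0][0]
    if measured_um <= 0:
        raise CalibrationError(f"{call.fibre_id}: degenerate motif span")
    motif_kb = (lmap.gmc_calibration_motif[1]
                - lmap.gmc_calibration_motif[0]) / 1_000.0
    call.stretch_estimate = motif_kb / measured_um
    return call.stretch_estimate


def measure_distances(call: FibreCall, fibre: Fibre,
                      lmap: Optional[LocusMap] = None,
                      merge_gap_kb: float = 1.0) -> dict:
    """Calibrated distance measurements; unavailable anchors are omitted.

    ``brca1_to_array_kb`` is measured from the designated BRCA1-end anchor
    bar to the inferred array start (first array signal minus the known
    label offset inside the unit).
    """
    lmap = lmap or default_locus_map()
    out: dict = {}
    if call.stretch_estimate is None:
        call.distances.update(out)
        return out
    stretch = call.stretch_estimate
    anchor = _bar_edge(call, lmap, lmap.brca1_anchor_element, stretch, "tel")
    lo = _bar_edge(call, lmap, "FP2", stretch, "tel")
    if anchor is not None and lo is not None:
        assigned = {i for idxs in call.matched_elements.values() for i in idxs}
        m = call.mirror_um
        reds = []
        for i, s in enumerate(fibre.signals):
            if s.channel != "R" or i in assigned:
                continue
            iv = (m - s.end_um, m - s.start_um) if call.mirrored \
                else (s.start_um, s.end_um)
            if (iv[0] + iv[1]) / 2.0 > lo:
                reds.append(iv)
        reds.sort()
        if reds:
            first_red = reds[0][0]
            out["brca1_to_array_kb"] = ((first_red - anchor) * stretch
                                        - LABEL_OFFSET / 1_000.0)
    if call.integrity == "full":
        _, _, reds = _array_red_signals(call, fibre, lmap, stretch)
        merged = _merge(reds, merge_gap_kb / stretch)
        out["signal_lengths_kb"] = [(e - s) * stretch for s, e in merged]
        out["gap_lengths_kb"] = [(s1 - e0) * stretch
                                 for (s0, e0), (s1, e1) in zip(merged, merged[1:])]
    call.distances.update(out)
    return out


def analyze_fibre(fibre: Fibre, lmap: Optional[LocusMap] = None,
                  tol_kb: float = 5.0, merge_gap_kb: float = 1.0,
                  min_elements: int = 4) -> FibreCall:
    """Full per-fibre pipeline: match, calibrate, gate, count, measure."""
    lmap = lmap or default_locus_map()
    call = match_barcode(fibre, lmap, tol_kb=tol_kb, min_elements=min_elements)
    try:
        calibrate_stretch(call, lmap)
    except CalibrationError:
        pass
    if call.integrity == "full":
        try:
            count_repeats(call, fibre, lmap, merge_gap_kb=merge_gap_kb)
        except GatingError:
            call.status = "unusable"
    measure_distances(call, fibre, lmap, merge_gap_kb=merge_gap_kb)
    return call


def analyze_fibres(fibres, lmap: Optional[LocusMap] = None,
                   **kwargs) -> list[FibreCall]:
    """Analyze a fibre table, logging gating statistics."""
    calls = [analyze_fibre(f, lmap, **kwargs) for f in fibres]
    n_count = sum(c.status == "countable" for c in calls)
    n_meas = sum(c.status == "measurable_only" for c in calls)
    n_bad = sum(c.status == "unusable" for c in calls)
    logger.info("analyzed %d fibres: %d countable, %d measurable-only, "
                "%d unusable", len(calls), n_count, n_meas, n_bad)
    return calls
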