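"""Readers and writers for the pipeline's plain-text formats.

Locus maps travel as BED9 (one record per probe bar, colour in itemRgb)
plus a YAML sidecar carrying the map constants and element metadata; fibre
tables, truth sidecars, calls, genotypes and allele tables are TSV
(pandas); placement evidence is TSV and placement results JSON.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence

import pandas as pd
import yaml

from .analyze import FibreCall
from .errors import ConfigError
from .locus import LocusMap, ProbeElement, RepeatUnitModel
from .placement import ContigEvidence, MatchSegment, PlacementResult
from .simulate import CohortDataset, Fibre, FibreTruth, Signal
from .stats import AlleleTable, Genotype

_RGB = {"red": "255,0,0", "green": "0,255,0", "blue": "0,0,255"}
_COLOR_FROM_RGB = {v: k for k, v in _RGB.items()}


# --- locus map -------------------------------------------------------------

def write_locus_bed(lmap: LocusMap, bed_path, yaml_path) -> None:
    """BED9 records (one per bar) plus a YAML constants sidecar."""
    with open(bed_path, "w") as fh:
        for el in lmap.elements:
            for s, e in el.bars:
                fh.write("\t".join([
                    lmap.reference_name, str(s), str(e), el.id, "0", ".",
                    str(s), str(e), _RGB[el.color]]) + "\n")
    meta = {
        "reference_name": lmap.reference_name,
        "array_anchor": list(lmap.array_anchor),
        "unit": {
            "unit_length": lmap.unit.unit_length,
            "labeled_intervals": [list(iv) for iv in lmap.unit.labeled_intervals],
            "color": lmap.unit.color,
        },
        "constants": {
            "flank_gap_centromeric": lmap.flank_gap_centromeric,
            "flank_gap_telomeric": lmap.flank_gap_telomeric,
            "gmc_calibration_motif": list(lmap.gmc_calibration_motif),
            "brca1_end_to_array_bp": lmap.brca1_end_to_array_bp,
            "array_to_rnu2_4p_bp": lmap.array_to_rnu2_4p_bp,
            "default_stretch": lmap.default_stretch,
            "brca1_anchor_element": lmap.brca1_anchor_element,
            "motif_start_element": lmap.motif_start_element,
            "motif_end_element": lmap.motif_end_element,
        },
        "roles": {el.id: el.role for el in lmap.elements},
    }
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_locus_bed(bed_path, yaml_path) -> LocusMap:
    with open(yaml_path) as fh:
        meta = yaml.safe_load(fh)
    bars: dict[str, list] = {}
    colors: dict[str, str] = {}
    order: list[str] = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            name, rgb = f[3], f[8]
            if name not in bars:
                bars[name] = []
                order.append(name)
            bars[name].append((int(f[1]), int(f[2])))
            colors[name] = _COLOR_FROM_RGB[rgb]
    elements = tuple(
        ProbeElement(name, colors[name], tuple(sorted(bars[name])),
                     meta["roles"][name])
        for name in order)
    unit = RepeatUnitModel(
        unit_length=meta["unit"]["unit_length"],
        labeled_intervals=tuple(tuple(iv)
                                for iv in meta["unit"]["labeled_intervals"]),
        color=meta["unit"]["color"])
    c = meta["constants"]
    return LocusMap(
        reference_name=meta["reference_name"], elements=elements,
        array_anchor=tuple(meta["array_anchor"]), unit=unit,
        flank_gap_centromeric=c["flank_gap_centromeric"],
        flank_gap_telomeric=c["flank_gap_telomeric"],
        gmc_calibration_motif=tuple(c["gmc_calibration_motif"]),
        brca1_end_to_array_bp=c["brca1_end_to_array_bp"],
        array_to_rnu2_4p_bp=c["array_to_rnu2_4p_bp"],
        default_stretch=c["default_stretch"],
        brca1_anchor_element=c["brca1_anchor_element"],
        motif_start_element=c["motif_start_element"],
        motif_end_element=c["motif_end_element"])


# --- fibres ----------------------------------------------------------------

def write_fibres_tsv(fibres: Sequence[Fibre], path) -> None:
    rows = [(f.fibre_id, f.individual_id, s.channel,
             f"{s.start_um:.4f}", f"{s.end_um:.4f}")
            for f in fibres for s in f.signals]
    pd.DataFrame(rows, columns=["fibre_id", "individual_id", "channel",
                                "start_um", "end_um"]).to_csv(
        path, sep="\t", index=False)


def read_fibres_tsv(path) -> list[Fibre]:
    df = pd.read_csv(path, sep="\t", dtype={"fibre_id": str,
                                            "individual_id": str})
    fibres = []
    for (fid, ind), grp in df.groupby(["fibre_id", "individual_id"],
                                      sort=False):
        signals = [Signal(r.channel, float(r.start_um), float(r.end_um))
                   for r in grp.itertuples()]
        signals.sort(key=lambda s: (s.start_um, s.end_um))
        fibres.append(Fibre(fid, ind, signals))
    return fibres


def write_truth_tsv(fibres: Sequence[Fibre], path) -> None:
    rows = []
    for f in fibres:
        t = f.truth
        if t is None:
            continue
        rows.append((f.fibre_id, t.haplotype, t.window_bp[0], t.window_bp[1],
                     f"{t.stretch_kb_per_um:.4f}", t.orientation))
    pd.DataFrame(rows, columns=["fibre_id", "haplotype", "window_start_bp",
                                "window_end_bp", "stretch_kb_per_um",
                                "orientation"]).to_csv(path, sep="\t",
                                                       index=False)


def write_cohort_truth(dataset: CohortDataset, genotypes_path) -> None:
    rows = [(f"I{i:03d}", a, b, int(u[0]), int(u[1]))
            for i, ((a, b), u) in enumerate(zip(dataset.genotypes,
                                                dataset.unrelated))]
    pd.DataFrame(rows, columns=["individual_id", "allele_1", "allele_2",
                                "unrelated_1", "unrelated_2"]).to_csv(
        genotypes_path, sep="\t", index=False)


def read_manifest(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    return {r.individual_id: (bool(r.unrelated_1), bool(r.unrelated_2))
            for r in df.itertuples()}


# --- calls / genotypes / tables --------------------------------------------

def write_calls_tsv(calls: Sequence[FibreCall], path) -> None:
    rows = []
    for c in calls:
        rows.append((
            c.fibre_id, c.individual_id, c.orientation,
            "" if c.stretch_estimate is None else f"{c.stretch_estimate:.4f}",
            c.integrity,
            "" if c.repeat_count is None else c.repeat_count,
            "" if "brca1_to_array_kb" not in c.distances
            else f"{c.distances['brca1_to_array_kb']:.2f}",
            c.status))
    pd.DataFrame(rows, columns=["fibre_id", "individual_id", "orientation",
                                "stretch_kb_per_um", "integrity",
                                "repeat_count", "brca1_to_array_kb",
                                "status"]).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> list[FibreCall]:
    df = pd.read_csv(path, sep="\t", dtype={"fibre_id": str,
                                            "individual_id": str})
    calls = []
    for r in df.itertuples():
        call = FibreCall(fibre_id=r.fibre_id, individual_id=r.individual_id,
                         orientation=r.orientation, integrity=r.integrity,
                         status=r.status)
        if pd.notna(r.stretch_kb_per_um):
            call.stretch_estimate = float(r.stretch_kb_per_um)
        if pd.notna(r.repeat_count):
            call.repeat_count = int(r.repeat_count)
        if pd.notna(r.brca1_to_array_kb):
            call.distances["brca1_to_array_kb"] = float(r.brca1_to_array_kb)
        calls.append(call)
    return calls


def write_genotypes_tsv(genotypes: Sequence[Genotype], path) -> None:
    rows = [(g.individual_id, g.allele_low, g.allele_high, g.support_low,
             g.support_high, int(g.heterozygous), g.confidence_note)
            for g in genotypes]
    pd.DataFrame(rows, columns=["individual_id", "allele_low", "allele_high",
                                "support_low", "support_high", "heterozygous",
                                "confidence_note"]).to_csv(path, sep="\t",
                                                           index=False)


def read_genotypes_tsv(path) -> list[Genotype]:
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    return [Genotype(r.individual_id, int(r.allele_low), int(r.allele_high),
                     int(r.support_low), int(r.support_high),
                     bool(r.heterozygous),
                     "" if pd.isna(r.confidence_note) else str(r.confidence_note))
            for r in df.itertuples()]


def write_allele_table_tsv(table: AlleleTable, path) -> None:
    pd.DataFrame(table.rows, columns=["repeat_units", "occurrences",
                                      "frequency"]).to_csv(
        path, sep="\t", index=False, float_format="%.2f")


# --- placement evidence ----------------------------------------------------

def write_evidence_tsv(evidence: Sequence[ContigEvidence], path) -> None:
    rows = []
    for ev in evidence:
        for s in ev.segments:
            rows.append((ev.contig_id, ev.length, s.contig_interval[0],
                         s.contig_interval[1], s.target, s.target_interval[0],
                         s.target_interval[1], s.orientation))
    pd.DataFrame(rows, columns=["contig_id", "contig_length", "contig_start",
                                "contig_end", "target", "target_start",
                                "target_end", "orientation"]).to_csv(
        path, sep="\t", index=False)


def read_evidence_tsv(path) -> list[ContigEvidence]:
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str})
    out = []
    for cid, grp in df.groupby("contig_id", sort=False):
        length = int(grp["contig_length"].max()) if "contig_length" in grp \
            else int(grp["contig_end"].max())
        segs = [MatchSegment(cid, (int(r.contig_start), int(r.contig_end)),
                             r.target, (int(r.target_start), int(r.target_end)),
                             r.orientation)
                for r in grp.itertuples()]
        out.append(ContigEvidence(cid, length, segs))
    return out


def write_placement_json(result: PlacementResult, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "array_interval": list(result.array_interval)
            if result.array_interval else None,
            "supporting_evidence": result.supporting_evidence,
            "flagged_contigs": [list(f) for f in result.flagged_contigs],
            "status": result.status,
        }, fh, indent=2)


# --- cohort config ---------------------------------------------------------

def read_cohort_config(path):
    from .simulate import CohortConfig
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = CohortConfig.__dataclass_fields__
    bad = set(raw) - set(known)
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    if "genotypes" in raw and raw["genotypes"] is not None:
        raw["genotypes"] = [tuple(g) for g in raw["genotypes"]]
    if "unrelated" in raw and raw["unrelated"] is not None:
        raw["unrelated"] = [tuple(bool(x) for x in u) for u in raw["unrelated"]]
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg
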