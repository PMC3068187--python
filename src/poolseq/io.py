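"""Readers and writers for the pipeline's on-disk formats.

BED target intervals (0-based half-open on disk, converted to the
package's 1-based inclusive convention and merged), VCF 4.x for truth
sets and call sets (via pysam; pools appear as VCF samples, since
individuals are unobservable in pooled data), a pileup-like TSV for
per-pool site counts, and YAML configs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .caller import SiteEvidence, VariantCall
from .design import PoolDesign
from .simulate import SiteCountsTable, TruthVariant

__all__ = [
    "read_bed",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_truth_vcf",
    "read_truth_vcf",
    "write_calls_vcf",
    "read_calls_vcf",
    "load_config",
    "save_config",
]


class BedParseError(ValueError):
    pass


def read_bed(path) -> tuple[list[tuple[str, int, int]], int]:
    """Parse a BED file into merged 1-based inclusive intervals.

    Returns (intervals, total_targeted_bases).  Overlapping or abutting
    intervals on the same contig are merged.
    """
    raw: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise BedParseError(f"line {lineno}: end must exceed start")
            raw.append((fields[0], start0 + 1, end0))  # to 1-based inclusive
    raw.sort()
    merged: list[tuple[str, int, int]] = []
    for contig, s, e in raw:
        if merged and merged[-1][0] == contig and s <= merged[-1][2] + 1:
            merged[-1] = (contig, merged[-1][1], max(merged[-1][2], e))
        else:
            merged.append((contig, s, e))
    total = sum(e - s + 1 for _, s, e in merged)
    return merged, total


# ---------------------------------------------------------------------------
# counts TSV

_COUNT_COLUMNS = [
    "contig",
    "position",
    "pool",
    "ref_allele",
    "alt_allele",
    "var_type",
    "depth",
    "ref_count",
    "alt_count",
    "other_count",
    "raw_depth",
    "mean_error_prob",
]


def write_counts_tsv(table: SiteCountsTable, path) -> None:
    ref_counts = table.ref
    rows = []
    for s in range(table.n_sites):
        for p in range(table.n_pools):
            rows.append(
                (
                    table.contig,
                    int(table.positions[s]),
                    p,
                    table.ref_alleles[s],
                    table.alt_alleles[s],
                    table.var_types[s],
                    int(table.depth[s, p]),
                    int(ref_counts[s, p]),
                    int(table.alt[s, p]),
                    int(table.other[s, p]),
                    int(table.raw_depth[s, p]),
                    float(table.mean_error_prob[s, p]),
                )
            )
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> SiteCountsTable:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts TSV missing columns: {sorted(missing)}")
    pools = sorted(df["pool"].unique())
    wide = df.set_index(["position", "pool"]).sort_index()
    positions = np.array(sorted(df["position"].unique()), dtype=np.int64)

    def grid(col, dtype):
        return np.array(
            [[wide.loc[(pos, p), col] for p in pools] for pos in positions], dtype=dtype
        )

    first = df.drop_duplicates("position").set_index("position").loc[positions]
    return SiteCountsTable(
        contig=str(df["contig"].iloc[0]),
        positions=positions,
        ref_alleles=list(first["ref_allele"]),
        alt_alleles=list(first["alt_allele"]),
        var_types=list(first["var_type"]),
        depth=grid("depth", np.int64),
        alt=grid("alt_count", np.int64),
        other=grid("other_count", np.int64),
        raw_depth=grid("raw_depth", np.int64),
        mean_error_prob=grid("mean_error_prob", float),
    )


# ---------------------------------------------------------------------------
# VCF

def _base_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    return header


def _contig_lengths(positions_by_contig: dict[str, int]) -> dict[str, int]:
    return {c: int(maxpos) + 1000 for c, maxpos in positions_by_contig.items()}


def write_truth_vcf(truth: Sequence[TruthVariant], design: PoolDesign, path) -> None:
    """Truth set as VCF; per-pool alt chromosome counts in INFO/PAC."""
    maxima: dict[str, int] = {}
    for tv in truth:
        maxima[tv.contig] = max(maxima.get(tv.contig, 0), tv.position + len(tv.ref_allele))
    header = _base_header(_contig_lengths(maxima) or {"target1": 1000})
    header.info.add("VT", 1, "String", "Variant type (SNV/insertion/deletion)")
    header.info.add("PF", 1, "Float", "Population alt allele frequency")
    header.info.add("PAC", ".", "Integer", "Per-pool alt chromosome counts")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for tv in sorted(truth, key=lambda v: (v.contig, v.position)):
            rec = vcf.new_record(
                contig=tv.contig,
                start=tv.position - 1,
                alleles=(tv.ref_allele, tv.alt_allele),
            )
            rec.info["VT"] = tv.var_type
            rec.info["PF"] = tv.population_frequency
            rec.info["PAC"] = list(tv.per_pool_alt_chromosomes)
            vcf.write(rec)


def read_truth_vcf(path) -> list[TruthVariant]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            pac = tuple(int(x) for x in rec.info["PAC"])
            out.append(
                TruthVariant(
                    contig=rec.contig,
                    position=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    var_type=str(rec.info["VT"]),
                    per_pool_alt_chromosomes=pac,
                    population_frequency=float(rec.info["PF"]),
                )
            )
    return out


def write_calls_vcf(calls: Sequence[VariantCall], design: PoolDesign, path) -> None:
    """Call set as VCF 4.x; pools are samples carrying DP/AD/EP/PEP."""
    maxima: dict[str, int] = {}
    for vc in calls:
        ev = vc.evidence
        maxima[ev.contig] = max(maxima.get(ev.contig, 0), ev.position + len(ev.ref_allele))
    header = _base_header(_contig_lengths(maxima) or {"target1": 1000})
    header.filters.add("min_alt_fail", None, None, "Fewer than min alt reads in every pool")
    header.filters.add("stat_fail", None, None, "Failed the error or cross-pool test")
    header.info.add("VT", 1, "String", "Variant type (SNV/insertion/deletion)")
    header.info.add("PE", 1, "Float", "Min per-pool binomial error-test p-value")
    header.info.add("PP", 1, "Float", "Cross-pool contingency p-value (nan if n/a)")
    header.formats.add("DP", 1, "Integer", "Filtered read depth")
    header.formats.add("AD", "R", "Integer", "Filtered read counts: ref, alt")
    header.formats.add("EP", 1, "Float", "Mean base error probability")
    header.formats.add("PEP", 1, "Float", "Per-pool binomial error-test p-value")
    for p in range(design.n_pools):
        header.add_sample(f"pool{p}")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for vc in sorted(calls, key=lambda c: (c.evidence.contig, c.evidence.position)):
            ev = vc.evidence
            rec = vcf.new_record(
                contig=ev.contig,
                start=ev.position - 1,
                alleles=(ev.ref_allele, ev.alt_allele),
            )
            rec.info["VT"] = vc.var_type
            rec.info["PE"] = vc.p_error
            rec.info["PP"] = vc.p_pool
            if vc.filter_status == "PASS":
                rec.filter.add("PASS")
            else:
                rec.filter.add(vc.filter_status)
            for p in range(design.n_pools):
                sample = rec.samples[f"pool{p}"]
                sample["DP"] = ev.depths[p]
                sample["AD"] = (ev.depths[p] - ev.alt_counts[p], ev.alt_counts[p])
                sample["EP"] = ev.mean_error_probs[p]
                sample["PEP"] = vc.p_error_per_pool[p]
            vcf.write(rec)


def read_calls_vcf(path) -> list[VariantCall]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            depths, alts, eps, peps = [], [], [], []
            for s in samples:
                sm = rec.samples[s]
                depths.append(int(sm["DP"]))
                alts.append(int(sm["AD"][1]))
                eps.append(float(sm["EP"]))
                peps.append(float(sm["PEP"]))
            status = list(rec.filter.keys())[0] if len(rec.filter) else "PASS"
            ev = SiteEvidence(
                contig=rec.contig,
                position=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                depths=tuple(depths),
                alt_counts=tuple(alts),
                mean_error_probs=tuple(eps),
                var_type=str(rec.info["VT"]),
            )
            out.append(
                VariantCall(
                    evidence=ev,
                    p_error=float(rec.info["PE"]),
                    p_error_per_pool=tuple(peps),
                    p_pool=float(rec.info["PP"]),
                    filter_status=status,
                    var_type=str(rec.info["VT"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# config

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def save_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
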