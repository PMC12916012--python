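"""Reading, harmonizing and windowing GWAS summary statistics.

The test consumes per-variant Z-scores (effect estimate divided by its
standard error) for two traits over one region, aligned to the allele
orientation of a shared LD reference.  This module covers the plumbing:
delimited-text ingestion with a configurable column map, allele
harmonization against a reference table, cis-window extraction
(gene +/- 1 Mb), minor-allele-frequency filtering, and the top-SNP
heritability ``h2 = Z**2 / (N + Z**2)`` used to design simulations.

Coordinates are 1-based closed intervals throughout (the GWAS summary
statistics convention); BED regions (0-based half-open) are converted on
read by :func:`read_regions_bed`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SumStats",
    "HarmonizeReport",
    "read_sumstats",
    "harmonize",
    "extract_cis_region",
    "filter_maf",
    "top_snp_h2",
    "read_regions_bed",
    "read_gene_table",
]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

CIS_WINDOW = 1_000_000  # +/- 1 Mb around the gene body


@dataclass
class SumStats:
    """Harmonizable per-variant summary statistics for one trait.

    ``N`` is per-variant; scalar input is broadcast.  ``chrom``/``pos``/
    ``maf`` are optional (None when the source lacks them).
    """

    variant_ids: np.ndarray
    z: np.ndarray
    N: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    trait_label: str = ""
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    maf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.variant_ids)
        self.N = np.broadcast_to(np.asarray(self.N, dtype=float), (n,)).copy()
        self.effect_allele = np.char.upper(
            np.asarray(self.effect_allele, dtype=str)
        ).astype(object)
        self.other_allele = np.char.upper(
            np.asarray(self.other_allele, dtype=str)
        ).astype(object)
        for name in ("z", "N", "effect_allele", "other_allele"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field {name!r} length mismatch")
        if len(set(self.variant_ids)) != n:
            raise ValueError("duplicate variant identifiers")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite Z-scores")
        if np.any(self.N <= 0):
            raise ValueError("sample sizes must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def median_N(self) -> float:
        """Region-level sample size used by the single-N likelihood."""
        return float(np.median(self.N))

    def subset(self, idx: np.ndarray) -> "SumStats":
        """Row subset / reorder by integer index or boolean mask."""
        kw = {}
        for name in ("chrom", "pos", "maf"):
            arr = getattr(self, name)
            kw[name] = None if arr is None else np.asarray(arr)[idx]
        return SumStats(
            variant_ids=self.variant_ids[idx],
            z=self.z[idx],
            N=self.N[idx],
            effect_allele=self.effect_allele[idx],
            other_allele=self.other_allele[idx],
            trait_label=self.trait_label,
            **kw,
        )


@dataclass
class HarmonizeReport:
    """Bookkeeping from one harmonization pass."""

    n_input: int
    n_retained: int
    n_flipped: int
    n_palindromic_dropped: int
    n_unmatched_dropped: int
    n_allele_mismatch_dropped: int


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_label: str = "",
    sep: str | None = None,
) -> tuple[SumStats, dict]:
    """Read delimited summary statistics into a :class:`SumStats`.

    ``column_map`` maps canonical names to file column names.  Required
    keys: ``id``, ``effect_allele``, ``other_allele``, ``n`` and either
    ``z`` or both ``beta`` and ``se`` (then ``z = beta / se``).  Optional:
    ``chrom``, ``pos``, ``maf``.  Rows with missing or non-finite values
    in any used column (including ``se == 0``) are dropped and counted in
    the returned report dict.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = ["id", "effect_allele", "other_allele", "n"]
    has_z = "z" in column_map
    required += ["z"] if has_z else ["beta", "se"]
    for key in required:
        if key not in column_map:
            raise ValueError(f"column_map is missing required key {key!r}")
        if column_map[key] not in df.columns:
            raise ValueError(
                f"mapped column {column_map[key]!r} (for {key!r}) not in file"
            )

    n_input = len(df)
    used = {k: column_map[k] for k in column_map if column_map[k] in df.columns}
    work = df[[used[k] for k in used]].copy()
    work.columns = list(used)

    if not has_z:
        se = pd.to_numeric(work["se"], errors="coerce")
        beta = pd.to_numeric(work["beta"], errors="coerce")
        se = se.where(se != 0)  # zero SE is unusable
        work["z"] = beta / se

    numeric = ["z", "n"] + [c for c in ("pos", "maf") if c in work]
    for col in numeric:
        work[col] = pd.to_numeric(work[col], errors="coerce")
    keep = np.isfinite(work[numeric]).all(axis=1)
    keep &= work["id"].notna() & work["effect_allele"].notna()
    keep &= work["other_allele"].notna() & (work["n"] > 0)
    n_dropped = int((~keep).sum())
    work = work[keep]
    if len(work) == 0:
        raise ValueError(f"no usable rows in {path}")

    ss = SumStats(
        variant_ids=work["id"].to_numpy(dtype=object),
        z=work["z"].to_numpy(),
        N=work["n"].to_numpy(),
        effect_allele=work["effect_allele"].astype(str).to_numpy(dtype=object),
        other_allele=work["other_allele"].astype(str).to_numpy(dtype=object),
        trait_label=trait_label,
        chrom=work["chrom"].astype(str).to_numpy(dtype=object) if "chrom" in work else None,
        pos=work["pos"].to_numpy() if "pos" in work else None,
        maf=work["maf"].to_numpy() if "maf" in work else None,
    )
    return ss, {"n_input": n_input, "n_dropped": n_dropped, "n_retained": len(work)}


def harmonize(
    ss: SumStats,
    ref_variant_ids,
    ref_effect_allele,
    ref_other_allele,
) -> tuple[SumStats, HarmonizeReport]:
    """Align a trait's Z-scores to a reference allele orientation.

    Variants are reordered to the reference order.  A variant whose
    (effect, other) pair is swapped relative to the reference has its Z
    sign flipped; strand-ambiguous palindromic variants (A/T, C/G) are
    dropped, as are variants absent from the reference or with alleles
    that match neither orientation.  Harmonizing an already-harmonized
    table is a no-op (zero flips).
    """
    ref_ids = [str(v) for v in ref_variant_ids]
    ref_ea = [str(a).upper() for a in ref_effect_allele]
    ref_oa = [str(a).upper() for a in ref_other_allele]
    lookup = {v: i for i, v in enumerate(ref_ids)}

    order: list[int] = []  # indices into ss, in ref order
    signs: list[float] = []
    n_flip = n_pal = n_unmatched = n_mismatch = 0
    pos_of = {v: i for i, v in enumerate(ss.variant_ids)}
    for rid in ref_ids:
        i = pos_of.get(rid)
        if i is None:
            continue
        ea, oa = ss.effect_allele[i], ss.other_allele[i]
        if (ea, oa) in PALINDROMIC:
            n_pal += 1
            continue
        j = lookup[rid]
        if ea == ref_ea[j] and oa == ref_oa[j]:
            order.append(i)
            signs.append(1.0)
        elif ea == ref_oa[j] and oa == ref_ea[j]:
            order.append(i)
            signs.append(-1.0)
            n_flip += 1
        else:
            n_mismatch += 1
    n_unmatched = ss.n_variants - len(order) - n_pal - n_mismatch

    if len(order) < 2:
        raise ValueError("fewer than 2 variants survive harmonization")
    out = ss.subset(np.asarray(order, dtype=int))
    out = replace(out, z=out.z * np.asarray(signs))
    # adopt the reference orientation for flipped variants
    flip = np.asarray(signs) < 0
    ea = out.effect_allele.copy()
    oa = out.other_allele.copy()
    ea[flip], oa[flip] = out.other_allele[flip], out.effect_allele[flip]
    out = replace(out, effect_allele=ea, other_allele=oa)
    report = HarmonizeReport(
        n_input=ss.n_variants,
        n_retained=out.n_variants,
        n_flipped=n_flip,
        n_palindromic_dropped=n_pal,
        n_unmatched_dropped=n_unmatched,
        n_allele_mismatch_dropped=n_mismatch,
    )
    return out, report


def extract_cis_region(
    ss: SumStats,
    gene_chrom,
    gene_start: int,
    gene_end: int,
    window: int = CIS_WINDOW,
) -> SumStats:
    """Variants within ``[gene_start - window, gene_end + window]`` on the
    gene's chromosome (closed interval, 1-based)."""
    if ss.pos is None or ss.chrom is None:
        raise ValueError("sumstats lack chrom/pos columns")
    lo, hi = gene_start - window, gene_end + window
    mask = (
        (np.asarray(ss.chrom).astype(str) == str(gene_chrom))
        & (ss.pos >= lo)
        & (ss.pos <= hi)
    )
    if not mask.any():
        raise ValueError("empty cis window")
    return ss.subset(mask)


def filter_maf(ss: SumStats, threshold: float = 0.05) -> SumStats:
    """Drop variants with minor allele frequency strictly below ``threshold``.

    MAF equal to the threshold is retained (the exclusion is strict).
    """
    if ss.maf is None:
        raise ValueError("sumstats lack a maf column")
    if np.any((ss.maf < 0) | (ss.maf > 0.5)):
        raise ValueError("maf values must lie in [0, 0.5]")
    return ss.subset(ss.maf >= threshold)


def top_snp_h2(ss: SumStats) -> float:
    """Heritability explained by the region's strongest single variant.

    Uses ``h2 = Z**2 / (N + Z**2)`` at the variant with the largest |Z|,
    with that variant's own sample size; sign-invariant, in [0, 1).
    """
    if ss.n_variants == 0:
        raise ValueError("empty sumstats")
    i = int(np.argmax(np.abs(ss.z)))
    z2 = float(ss.z[i]) ** 2
    n = float(ss.N[i])
    if n <= 0:
        raise ValueError("non-positive sample size")
    return z2 / (n + z2)


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    """BED regions (0-based half-open) to 1-based closed gene intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "gene"],
    )
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df[["gene", "chrom", "start", "end"]]


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Simple gene table with header columns gene, chrom, start, end
    (1-based closed)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"gene", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return df[["gene", "chrom", "start", "end"]]
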