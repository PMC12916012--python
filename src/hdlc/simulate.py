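"""Synthetic data generation: causal effects, phenotypes, GWAS Z-scores.

Three simulation routes, from slowest/most explicit to fastest:

``individual``
    Standardized-Gaussian genotypes with the block's LD, phenotypes from
    the polygenic model ``y = X[:, causal] @ beta + eps`` with residual
    variance ``1 - h2`` (total phenotypic variance 1), and per-variant
    marginal regression Z-scores.

``direct`` (conditional on effects)
    Skips genotypes: given drawn causal effects beta, marginal Z-scores
    are sampled from their large-N conditional law
    ``z | beta ~ N(sqrt(N) * R @ beta, R)``.  This respects any causal
    architecture (a fraction or a count of causal variants) and reduces
    to the model's own marginal multivariate normal when every variant
    is causal.

model MVN (:func:`simulate_sumstats_direct`)
    Samples Z-score pairs straight from the likelihood's bivariate
    Gaussian with parameters (h1^2, h2^2, h12) — the infinitesimal
    architecture, one independent 2x2 draw per retained eigenvalue.

Causal effects are bivariate normal per causal variant j:

    (beta_1j, beta_2j) ~ N(0, [[h1^2/m, rG*sqrt(h1^2 h2^2)/m],
                               [  (sym), h2^2/m]]),

with m the causal count, so regional heritabilities and the local
genetic correlation equal their target values in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colocalization import hdlc_test
from .ldmodel import LDBlock, simulate_ld_ar1

__all__ = [
    "SimScenario",
    "draw_effects",
    "simulate_genotypes",
    "simulate_phenotypes",
    "gwas_zscores",
    "simulate_sumstats_direct",
    "simulate_sumstats_from_effects",
    "sample_top_snp_h2",
    "run_scenario",
    "write_scenario",
    "read_scenario",
]

R_CLIP = 1.0 - 1e-12  # guards the z transform at perfect correlation

# Synthetic stand-in for the top-SNP heritability distribution of
# catalogued cis-pQTLs: log-normal on the h2 scale, median 0.03,
# sigma(log) = 1.2.  Matches the order of magnitude implied by
# h2 = Z^2/(N + Z^2) at proteomics-GWAS scale (N ~ 3e4, top-SNP Z ~ 10-100).
# The lower clip reflects ascertainment: a region enters a cis-pQTL
# catalogue only with a genome-wide-significant top SNP (|Z| ~ 5.5 at
# N ~ 3e4 gives h2 ~ 1e-3), so smaller values cannot occur.
_TOP_SNP_H2_LOG_MEDIAN = float(np.log(0.03))
_TOP_SNP_H2_LOG_SIGMA = 1.2
_TOP_SNP_H2_RANGE = (1e-3, 0.5)


def sample_top_snp_h2(rng: np.random.Generator, size: int | None = None):
    """Draw protein-trait regional heritabilities from the built-in
    synthetic top-SNP stand-in distribution (see module constants)."""
    draw = rng.lognormal(_TOP_SNP_H2_LOG_MEDIAN, _TOP_SNP_H2_LOG_SIGMA, size=size)
    return np.clip(draw, *_TOP_SNP_H2_RANGE)


def draw_effects(
    m: int,
    h1_sq: float,
    h2_sq: float,
    rg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-causal-variant effect pairs with the target bivariate covariance.

    Uses an explicit Cholesky-style construction so the degenerate cases
    rG = +/-1 are exact (beta2 proportional to beta1).
    """
    if m < 1:
        raise ValueError("need at least one causal variant")
    if abs(rg) > 1:
        raise ValueError("|rG| must be <= 1")
    if h1_sq < 0 or h2_sq < 0:
        raise ValueError("heritabilities must be >= 0")
    x = rng.standard_normal(m)
    y = rng.standard_normal(m)
    beta1 = np.sqrt(h1_sq / m) * x
    beta2 = np.sqrt(h2_sq / m) * (rg * x + np.sqrt(max(0.0, 1.0 - rg**2)) * y)
    return beta1, beta2


def simulate_genotypes(
    N: int,
    block: LDBlock,
    rng: np.random.Generator,
    discretize: bool = False,
    maf: float | np.ndarray = 0.25,
) -> np.ndarray:
    """Column-standardized genotypes whose correlation converges to R.

    Rows are drawn from N(0, R) via the block's eigen square root, then
    each column is centered and scaled to unit variance.  With
    ``discretize=True`` the latent Gaussians are cut at copula thresholds
    for the given MAF into additive 0/1/2 dosages before standardization
    (off by default: the likelihood sees only Z-scores, so dosage
    discreteness is immaterial to the target quantities).
    """
    if N < 2:
        raise ValueError("need at least 2 individuals")
    F = block.sqrt_factor()
    X = rng.standard_normal((N, F.shape[1])) @ F.T
    if discretize:
        from scipy import stats as _stats

        p = np.broadcast_to(np.asarray(maf, dtype=float), (block.M,))
        # two independent haplotypes share the column's LD-derived quantile cut
        q = _stats.norm.ppf(1.0 - p)
        X2 = rng.standard_normal((N, F.shape[1])) @ F.T
        X = (X > q).astype(float) + (X2 > q).astype(float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("zero-variance genotype column; increase N")
    return X / sd


def simulate_phenotypes(
    X: np.ndarray,
    causal_idx: np.ndarray,
    beta: np.ndarray,
    h_sq: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Polygenic phenotype: genetic value plus N(0, 1 - h2) residual."""
    causal_idx = np.asarray(causal_idx, dtype=int)
    beta = np.asarray(beta, dtype=float)
    if len(causal_idx) != len(beta):
        raise ValueError("causal_idx and beta lengths differ")
    if not 0.0 <= h_sq < 1.0:
        raise ValueError("h_sq must lie in [0, 1)")
    genetic = X[:, causal_idx] @ beta
    return genetic + rng.normal(0.0, np.sqrt(1.0 - h_sq), size=X.shape[0])


def gwas_zscores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Marginal association Z-scores of each column of X against y.

    Equivalent to the per-variant simple-regression slope over its
    standard error, computed through the correlation identity
    ``z = sqrt(N - 2) * r / sqrt(1 - r^2)`` with |r| clipped just below 1
    so collinear degenerate columns give finite, huge Z.
    """
    N = X.shape[0]
    yc = y - y.mean()
    sy = yc.std()
    sx = X.std(axis=0)
    if sy == 0 or np.any(sx == 0):
        raise ValueError("zero-variance phenotype or genotype column")
    r = (X - X.mean(axis=0)).T @ yc / (N * sx * sy)
    r = np.clip(r, -R_CLIP, R_CLIP)
    return np.sqrt(N - 2) * r / np.sqrt(1.0 - r**2)


def simulate_sumstats_direct(
    block: LDBlock,
    h1_sq: float,
    h2_sq: float,
    h12: float,
    N1: float,
    N2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a Z-score pair from the model's own multivariate normal.

    One independent bivariate draw per retained eigenvalue, back-rotated
    to variant space — the exact distribution the likelihood evaluates,
    orders of magnitude faster than the individual-level route.
    """
    bound = np.sqrt(h1_sq * h2_sq)
    if abs(h12) > bound + 1e-12:
        raise ValueError("|h12| exceeds sqrt(h1_sq * h2_sq)")
    lam = block.eigvals
    M = block.M
    d1 = N1 * h1_sq * lam**2 / M + lam
    d2 = N2 * h2_sq * lam**2 / M + lam
    c = np.sqrt(N1 * N2) * h12 * lam**2 / M
    # per-eigenvalue 2x2 Cholesky
    l11 = np.sqrt(d1)
    l21 = c / l11
    l22 = np.sqrt(np.maximum(d2 - l21**2, 0.0))
    g1 = rng.standard_normal(lam.shape[0])
    g2 = rng.standard_normal(lam.shape[0])
    w1 = l11 * g1
    w2 = l21 * g1 + l22 * g2
    return block.eigvecs @ w1, block.eigvecs @ w2


def simulate_sumstats_from_effects(
    block: LDBlock,
    beta1: np.ndarray,
    beta2: np.ndarray,
    causal_idx: np.ndarray,
    N1: float,
    N2: float,
    rng: np.random.Generator,
    causal_idx2: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample Z-scores conditional on fixed causal effects.

    Uses the large-N law of marginal statistics on standardized data:
    ``z_i | beta_i ~ N(sqrt(N_i) * R @ beta_i, R)``.  Architecture-aware
    (only causal columns carry signal) and much faster than simulating
    genotypes.  ``causal_idx2`` lets the second trait carry its effects
    at different variants (non-colocalized regions); default is a shared
    causal set.
    """
    causal_idx = np.asarray(causal_idx, dtype=int)
    if causal_idx2 is None:
        causal_idx2 = causal_idx
    causal_idx2 = np.asarray(causal_idx2, dtype=int)
    full1 = np.zeros(block.M)
    full2 = np.zeros(block.M)
    full1[causal_idx] = beta1
    full2[causal_idx2] = beta2
    F = block.sqrt_factor()
    K = F.shape[1]
    z1 = np.sqrt(N1) * block.R @ full1 + F @ rng.standard_normal(K)
    z2 = np.sqrt(N2) * block.R @ full2 + F @ rng.standard_normal(K)
    return z1, z2


@dataclass
class SimScenario:
    """Full specification of one simulation grid.

    ``architecture`` is either a causal fraction in (0, 1] (e.g. 0.10) or
    an integer causal count (1, 3, 5).  ``h1_sq_grid`` may be the string
    ``"top-snp"`` to resample the protein-trait heritability per replicate
    from the built-in synthetic top-SNP stand-in distribution, or an
    explicit list of values to cycle through.
    """

    M: int = 500
    ld_rho: float = 0.9
    architecture: float | int = 0.10
    h1_sq_grid: Sequence[float] | str = (0.05,)
    h2_sq_grid: Sequence[float] = (0.001, 0.01, 0.1)
    rg_grid: Sequence[float] = (0.0, 0.3, 0.5, 0.8, 1.0)
    N1: float = 30_000
    N2: float = 300_000
    n_replicates: int = 100
    mode: str = "direct"  # "direct" (effect-conditional) or "individual"
    seed: int = 0
    ld_file: str | None = None
    ld_snplist: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "individual"):
            raise ValueError("mode must be 'direct' or 'individual'")
        if isinstance(self.architecture, float) and not 0 < self.architecture <= 1:
            raise ValueError("causal fraction must be in (0, 1]")
        if isinstance(self.architecture, int) and self.architecture < 1:
            raise ValueError("causal count must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for rg in self.rg_grid:
            if abs(rg) > 1:
                raise ValueError("rG grid values must lie in [-1, 1]")
        if isinstance(self.h1_sq_grid, str) and self.h1_sq_grid != "top-snp":
            raise ValueError("h1_sq_grid must be a list of values or 'top-snp'")
        grids = [self.h2_sq_grid, self.rg_grid]
        if not isinstance(self.h1_sq_grid, str):
            grids.append(self.h1_sq_grid)
        for g in grids:
            if len(g) == 0:
                raise ValueError("empty grid")
        for g in (self.h2_sq_grid,) + (
            () if isinstance(self.h1_sq_grid, str) else (tuple(self.h1_sq_grid),)
        ):
            for h in g:
                if not 0 <= h < 1:
                    raise ValueError("h^2 grid values must lie in [0, 1)")

    def n_causal(self) -> int:
        if isinstance(self.architecture, int):
            return min(self.architecture, self.M)
        return max(1, int(round(self.architecture * self.M)))

    def build_block(self) -> LDBlock:
        if self.ld_file is not None:
            from . import ldmodel

            if self.ld_snplist is not None:
                return ldmodel.read_ld_binary(self.ld_file, self.ld_snplist)
            return ldmodel.read_ld_text(self.ld_file)
        return simulate_ld_ar1(self.M, self.ld_rho)


def _replicate_seed(base_seed: int, cell: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=base_seed, spawn_key=(cell, rep))
    )


def _one_replicate(
    scenario: SimScenario,
    block: LDBlock,
    h1_sq: float,
    h2_sq: float,
    rg: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    m = scenario.n_causal()
    # Count-causal (sparse) regions with rG = 0 represent non-colocalized
    # loci: each trait gets its own independently placed causal set.  With
    # a single shared causal variant, independent effect draws would still
    # be perfectly proportional within a replicate, which is not a usable
    # negative.  Fraction-causal (polygenic) regions share the causal set
    # and rely on the effect correlation alone.
    sparse_null = isinstance(scenario.architecture, int) and rg == 0
    causal1 = rng.choice(block.M, size=m, replace=False)
    if sparse_null:
        causal2 = rng.choice(block.M, size=m, replace=False)
        beta1, _ = draw_effects(m, h1_sq, h2_sq, 0.0, rng)
        _, beta2 = draw_effects(m, h1_sq, h2_sq, 0.0, rng)
    else:
        causal2 = causal1
        beta1, beta2 = draw_effects(m, h1_sq, h2_sq, rg, rng)
    if scenario.mode == "individual":
        X1 = simulate_genotypes(int(scenario.N1), block, rng)
        y1 = simulate_phenotypes(X1, causal1, beta1, h1_sq, rng)
        z1 = gwas_zscores(X1, y1)
        X2 = simulate_genotypes(int(scenario.N2), block, rng)
        y2 = simulate_phenotypes(X2, causal2, beta2, h2_sq, rng)
        z2 = gwas_zscores(X2, y2)
        return z1, z2
    return simulate_sumstats_from_effects(
        block, beta1, beta2, causal1, scenario.N1, scenario.N2, rng,
        causal_idx2=causal2,
    )


def run_scenario(
    scenario: SimScenario,
    r0_list: Sequence[float] = (0.0, 0.5),
    out_path: str | Path | None = None,
    compute_ci: bool = False,
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full grid x replicates and collect one row per (replicate, r0).

    Per-replicate randomness is derived deterministically from the
    scenario seed and the grid coordinates, so reruns reproduce the table
    exactly and completed cells found in ``existing`` are skipped
    (resumable runs).  Replicate-level failures are recorded as flagged
    rows, never raised.  When ``out_path`` is given rows are appended to a
    TSV as they complete.
    """
    block = scenario.build_block()
    h1_values = (
        None if isinstance(scenario.h1_sq_grid, str) else list(scenario.h1_sq_grid)
    )
    h2_values = list(scenario.h2_sq_grid)
    rg_values = list(scenario.rg_grid)

    done: set[tuple] = set()
    if existing is not None and len(existing):
        done = {
            (r.cell, r.replicate, float(r.r0))
            for r in existing.itertuples(index=False)
        }

    cells = []
    cell_id = 0
    for h1 in h1_values if h1_values is not None else [None]:
        for h2 in h2_values:
            for rg in rg_values:
                cells.append((cell_id, h1, h2, rg))
                cell_id += 1

    rows = []
    out_path = Path(out_path) if out_path is not None else None
    header_written = out_path is not None and out_path.exists() and out_path.stat().st_size > 0
    for cid, h1, h2, rg in cells:
        for rep in range(scenario.n_replicates):
            pending_r0 = [
                r0 for r0 in r0_list if (cid, rep, float(r0)) not in done
            ]
            if not pending_r0:
                continue
            rng = _replicate_seed(scenario.seed, cid, rep)
            h1_rep = float(sample_top_snp_h2(rng)) if h1 is None else h1
            new_rows = []
            try:
                z1, z2 = _one_replicate(scenario, block, h1_rep, h2, rg, rng)
                for r0 in pending_r0:
                    res = hdlc_test(
                        block, z1, z2, scenario.N1, scenario.N2,
                        r0=r0, compute_ci=compute_ci,
                    )
                    new_rows.append(
                        {
                            "cell": cid,
                            "replicate": rep,
                            "true_h1_sq": h1_rep,
                            "true_h2_sq": h2,
                            "true_rg": rg,
                            "architecture": scenario.architecture,
                            "r0": r0,
                            "h1_hat": res.params_hat.h1_sq,
                            "h2_hat": res.params_hat.h2_sq,
                            "h12_hat": res.params_hat.h12,
                            "rg_hat": np.nan if res.rg_hat is None else res.rg_hat,
                            "lambda": res.lam,
                            "pvalue": res.pvalue,
                            "ci_low": np.nan if res.rg_ci_low is None else res.rg_ci_low,
                            "ci_high": np.nan if res.rg_ci_high is None else res.rg_ci_high,
                            "flags": ";".join(res.flags),
                        }
                    )
            except Exception as exc:  # replicate failures are data, not fatal
                for r0 in pending_r0:
                    new_rows.append(
                        {
                            "cell": cid, "replicate": rep,
                            "true_h1_sq": h1_rep, "true_h2_sq": h2, "true_rg": rg,
                            "architecture": scenario.architecture, "r0": r0,
                            "h1_hat": np.nan, "h2_hat": np.nan, "h12_hat": np.nan,
                            "rg_hat": np.nan, "lambda": np.nan, "pvalue": np.nan,
                            "ci_low": np.nan, "ci_high": np.nan,
                            "flags": f"failed:{type(exc).__name__}",
                        }
                    )
            rows.extend(new_rows)
            if out_path is not None and new_rows:
                chunk = pd.DataFrame(new_rows)
                chunk.to_csv(
                    out_path, sep="\t", index=False,
                    mode="a" if header_written else "w",
                    header=not header_written,
                )
                header_written = True

    df = pd.DataFrame(rows)
    if existing is not None and len(existing):
        df = pd.concat([existing, df], ignore_index=True)
    return df


def write_scenario(scenario: SimScenario, path: str | Path) -> None:
    """Serialize a scenario to a flat key=value text file."""
    lines = []
    for key, val in vars(scenario).items():
        if isinstance(val, (list, tuple)):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario(path: str | Path) -> SimScenario:
    """Parse a flat key=value scenario file written by :func:`write_scenario`."""
    kwargs: dict = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if raw == "None":
            kwargs[key] = None
        elif key in ("h1_sq_grid", "h2_sq_grid", "rg_grid"):
            if key == "h1_sq_grid" and raw == "top-snp":
                kwargs[key] = "top-snp"
            else:
                kwargs[key] = tuple(float(v) for v in raw.split(","))
        elif key in ("M", "n_replicates", "seed"):
            kwargs[key] = int(raw)
        elif key == "architecture":
            kwargs[key] = int(raw) if "." not in raw else float(raw)
        elif key in ("ld_rho", "N1", "N2"):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return SimScenario(**kwargs)
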