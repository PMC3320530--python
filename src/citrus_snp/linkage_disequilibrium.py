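"""Pairwise linkage disequilibrium on unphased diploid genotypes.

r² is the squared Pearson correlation of allele-dosage vectors
(0/1/2 copies of the B allele) over pairwise-complete accessions —
the composite, phase-free LD measure.  Significance comes from a
seeded Monte-Carlo permutation test (one dosage vector shuffled).
In a structured germplasm panel even unlinked loci show elevated r²;
in an F1 progeny of unlinked loci r² has null expectation ≈ 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from citrus_snp.genotype_io import GenotypeMatrix, AA, AB, BB, observable_codes


@dataclass
class LDResult:
    locus_a: str
    locus_b: str
    r2: float
    p_value: float | None
    n: int


def _dosage_matrix(gm: GenotypeMatrix, loci, accessions) -> np.ndarray:
    sub = gm.subset(accessions=accessions, loci=loci)
    codes = observable_codes(sub.calls)
    return np.select([codes == AA, codes == AB, codes == BB],
                     [0.0, 1.0, 2.0], default=np.nan)


def _em_haplotype_r2(x: np.ndarray, y: np.ndarray,
                     max_iter: int = 200, tol: float = 1e-10) -> float:
    """Two-locus EM haplotype-frequency estimate of r² from unphased
    dosages: only double heterozygotes are phase-ambiguous."""
    n = len(x)
    cnt = np.zeros((3, 3))
    for i, j in zip(x.astype(int), y.astype(int)):
        cnt[i, j] += 1
    pA, pB = x.mean() / 2, y.mean() / 2
    p11 = pA * pB
    p10 = pA - p11
    p01 = pB - p11
    p00 = 1 - p11 - p10 - p01
    for _ in range(max_iter):
        den = p11 * p00 + p10 * p01
        f = p11 * p00 / den if den > 0 else 0.5
        c11 = 2 * cnt[2, 2] + cnt[2, 1] + cnt[1, 2] + f * cnt[1, 1]
        c10 = 2 * cnt[2, 0] + cnt[2, 1] + cnt[1, 0] + (1 - f) * cnt[1, 1]
        c01 = 2 * cnt[0, 2] + cnt[1, 2] + cnt[0, 1] + (1 - f) * cnt[1, 1]
        c00 = 2 * cnt[0, 0] + cnt[1, 0] + cnt[0, 1] + f * cnt[1, 1]
        new = np.array([c11, c10, c01, c00]) / (2 * n)
        if np.abs(new - [p11, p10, p01, p00]).max() < tol:
            p11, p10, p01, p00 = new
            break
        p11, p10, p01, p00 = new
    pA, pB = p11 + p10, p11 + p01
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        return float("nan")
    d = p11 - pA * pB
    return float(d * d / denom)


def ld_r2(gm: GenotypeMatrix, locus_a: str, locus_b: str,
          accessions: list[str] | None = None,
          permutations: int = 0, seed: int = 0,
          min_n: int = 5, method: str = "composite") -> LDResult:
    """r² for one locus pair, with an optional permutation p-value.

    ``method="composite"`` (default) is the squared dosage correlation;
    ``method="em"`` estimates two-locus haplotype frequencies by EM
    (double heterozygotes phase-resolved iteratively) and returns the
    classical D²-based r².  Raises when either locus has zero dosage
    variance or fewer than `min_n` pairwise-complete accessions remain.
    """
    if method not in {"composite", "em"}:
        raise ValueError(f"unknown method {method!r}")
    d = _dosage_matrix(gm, [locus_a, locus_b], accessions)
    x, y = d[:, 0], d[:, 1]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < min_n:
        raise ValueError(f"only {n} pairwise-complete accessions")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero dosage variance at a locus")
    if method == "em":
        r2 = _em_haplotype_r2(x, y)
    else:
        r = float(np.corrcoef(x, y)[0, 1])
        r2 = r * r
    if method == "em":
        def stat(yy):
            return _em_haplotype_r2(x, yy)
    else:
        def stat(yy):
            r = np.corrcoef(x, yy)[0, 1]
            return r * r
    p = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = sum(stat(rng.permutation(y)) >= r2 - 1e-12
                   for _ in range(permutations))
        p = (hits + 1) / (permutations + 1)
    return LDResult(locus_a, locus_b, r2, p, n)


def ld_matrix(gm: GenotypeMatrix, loci: list[str] | None = None,
              accessions: list[str] | None = None,
              min_n: int = 5) -> pd.DataFrame:
    """All-pairs r² table (columns locus_a, locus_b, r2, n), pairwise-
    complete; monomorphic loci and under-observed pairs are skipped."""
    sub = gm.subset(accessions=accessions, loci=loci)
    d = _dosage_matrix(sub, None, None)
    df = pd.DataFrame(d, columns=sub.locus_ids)
    # drop loci without dosage variance up-front
    keep = [c for c in df.columns if df[c].std(skipna=True) > 0
            and df[c].notna().sum() >= min_n]
    df = df[keep]
    corr = df.corr(method="pearson", min_periods=min_n)
    counts = df.notna().astype(int).T @ df.notna().astype(int)
    rows = []
    cols = list(df.columns)
    r2v = corr.to_numpy() ** 2
    nv = counts.to_numpy()
    for i, j in combinations(range(len(cols)), 2):
        if np.isnan(r2v[i, j]) or nv[i, j] < min_n:
            continue
        rows.append((cols[i], cols[j], float(r2v[i, j]), int(nv[i, j])))
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "r2", "n"])


@dataclass
class LDSummary:
    n_pairs: int
    mean_r2: float
    n_above_threshold: int
    percent_above_threshold: float
    n_significant: dict[float, int]


def ld_summary(results: pd.DataFrame, r2_threshold: float = 0.2,
               alpha_levels: tuple[float, ...] = (0.05, 0.01)) -> LDSummary:
    """Panel-level LD summary: mean r², count/percent of pairs above
    the r² threshold, and counts under each significance level when a
    p_value column is present."""
    if results.empty:
        raise ValueError("no LD results to summarize")
    r2 = results["r2"].to_numpy()
    above = int((r2 > r2_threshold).sum())
    sig = {}
    if "p_value" in results.columns:
        p = results["p_value"].to_numpy()
        sig = {a: int((p < a).sum()) for a in alpha_levels}
    return LDSummary(n_pairs=len(r2), mean_r2=float(r2.mean()),
                     n_above_threshold=above,
                     percent_above_threshold=100.0 * above / len(r2),
                     n_significant=sig)
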