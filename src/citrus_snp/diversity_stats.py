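"""Diversity and F-statistics for grouped diploid SNP genotypes.

Observed heterozygosity (Ho), Nei expected heterozygosity (He = 1 - Σp²),
multilocus-genotype counts, genotypic diversity (GD = 1 - Σg² over
observed genotype-state frequencies, used where null alleles make allele
frequencies unobservable), the fixation index F = 1 - Ho/He, and
Weir-Cockerham variance-component F-statistics (Fis, Fit, Fst) combined
over loci with delete-one-locus jackknife standard errors.

All statistics operate on array-observable states: a null heterozygote
is counted as the homozygote it resembles, exactly as the platform
reports it.  Null homozygotes (``00``) are tracked separately and, in
null-aware mode, removed from heterozygosity denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from citrus_snp.genotype_io import (
    GenotypeMatrix, PopulationScheme, AA, AB, BB, NULL2, MISSING,
    observable_codes,
)


def nei_he(freqs) -> float:
    """Nei gene diversity He = 1 - Σ p_i² for one locus.

    `freqs` are allele frequencies summing to 1; for a biallelic locus
    He is at most 0.5, and He = 0.095 marks a minor-allele frequency of
    0.05 (the conventional rare-allele boundary).
    """
    p = np.asarray(freqs, dtype=float)
    if p.size == 0 or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(p ** 2))


@dataclass
class DiversitySummary:
    """Per-group diversity row (the shape of a germplasm summary table)."""
    group: str
    n_accessions: int
    percent_polymorphic: float
    n_mlg: int
    ho: float
    ho_se: float
    he: float
    he_se: float
    f: float                     # 1 - Ho/He; NaN when He is 0
    gd: float                    # genotypic diversity (null-aware mode)
    gd_se: float
    null_homozygote_freq: float  # frequency of 00 states (null-aware mode)


def _allele_freqs_B(obs: np.ndarray) -> np.ndarray:
    """Per-locus frequency of allele B from observable codes, ignoring
    missing and null-homozygous cells; NaN where no A/B call exists."""
    called = np.isin(obs, (AA, AB, BB))
    nB = np.where(called, np.select(
        [obs == AA, obs == AB, obs == BB], [0, 1, 2], 0), 0).sum(axis=0)
    n2 = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n2 > 0, nB / n2, np.nan)


def _se(values: np.ndarray) -> float:
    v = values[~np.isnan(values)]
    if v.size < 2:
        return 0.0
    return float(v.std(ddof=1) / np.sqrt(v.size))


def group_summary(gm: GenotypeMatrix, scheme: PopulationScheme,
                  loci: list[str] | None = None,
                  null_aware: bool = False,
                  include_all: bool = True,
                  unbiased_he: bool = False) -> dict[str, DiversitySummary]:
    """Diversity summary per taxon group (germplasm accessions only),
    plus an ``All samples`` row.

    In null-aware mode (the with-null-allele marker sets) ``00`` counts
    as an observable genotype state for polymorphism, multilocus
    genotypes and GD, while Ho excludes null homozygotes from its
    denominator and the ``00`` frequency is reported separately.

    ``unbiased_he`` applies the 2n/(2n-1) small-sample correction.
    """
    sub = gm.subset(loci=loci) if loci is not None else gm
    obs_all = observable_codes(sub.calls)
    germ = set(scheme.germplasm)
    blocks: list[tuple[str, list[str]]] = [
        (g, [a for a in members if a in germ])
        for g, members in scheme.groups.items()]
    for g, m in blocks:
        if not m:
            raise ValueError(f"group {g} has no germplasm accessions")
    if include_all:
        all_members = [a for _, m in blocks for a in m]
        blocks.append(("All samples", all_members))
    out: dict[str, DiversitySummary] = {}
    for name, members in blocks:
        if not members:
            raise ValueError(f"group {name} has no germplasm accessions")
        rows = [sub.acc_idx(a) for a in members]
        obs = obs_all[rows]
        typed = obs != MISSING
        called = np.isin(obs, (AA, AB, BB))
        valid_states = typed if null_aware else called

        # polymorphism: >= 2 observed states within the group
        n_states = np.zeros(sub.n_loci, dtype=int)
        for code in (AA, AB, BB, NULL2):
            if code == NULL2 and not null_aware:
                continue
            n_states += (obs == code).any(axis=0)
        informative = valid_states.any(axis=0)
        pct_poly = 100.0 * (n_states >= 2).sum() / max(informative.sum(), 1)

        # multilocus genotypes: distinct observable rows
        n_mlg = len({tuple(r) for r in obs})

        # Ho per locus: het calls over typed (null-aware: 00 excluded)
        denom = valid_states.sum(axis=0).astype(float)
        if null_aware:
            denom = (typed & (obs != NULL2)).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_l = np.where(denom > 0,
                            (obs == AB).sum(axis=0) / denom, np.nan)

        # He per locus from A/B allele frequencies
        pB = _allele_freqs_B(obs)
        with np.errstate(invalid="ignore"):
            he_l = 2.0 * pB * (1.0 - pB)
        if unbiased_he:
            n_called = called.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                corr = np.where(n_called > 0,
                                2.0 * n_called / (2.0 * n_called - 1.0), 1.0)
            he_l = he_l * corr

        # GD per locus over observed genotype-state frequencies
        gd_l = np.full(sub.n_loci, np.nan)
        for j in range(sub.n_loci):
            col = obs[typed[:, j], j] if not null_aware else obs[:, j][typed[:, j]]
            if col.size == 0:
                continue
            _, counts = np.unique(col, return_counts=True)
            g = counts / counts.sum()
            gd_l[j] = 1.0 - np.sum(g ** 2)

        ho = float(np.nanmean(ho_l)) if np.any(~np.isnan(ho_l)) else np.nan
        he = float(np.nanmean(he_l)) if np.any(~np.isnan(he_l)) else np.nan
        f = 1.0 - ho / he if he and he > 0 else float("nan")
        n00 = (obs == NULL2).sum()
        null_freq = float(n00 / max(typed.sum(), 1))
        out[name] = DiversitySummary(
            group=name, n_accessions=len(members),
            percent_polymorphic=float(pct_poly), n_mlg=n_mlg,
            ho=ho, ho_se=_se(ho_l), he=he, he_se=_se(he_l), f=f,
            gd=float(np.nanmean(gd_l)), gd_se=_se(gd_l),
            null_homozygote_freq=null_freq)
    return out


def summary_frame(summaries: dict[str, DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries.values()]).set_index("group")


# ---------------------------------------------------------------------------
# Weir-Cockerham F-statistics

@dataclass
class FStatResult:
    fis: float
    fit: float
    fst: float
    fis_se: float
    fit_se: float
    fst_se: float
    per_locus: pd.DataFrame      # columns a, b, c, fst (NaN where undefined)
    n_loci: int


def _wc_components(counts: np.ndarray) -> tuple[float, float, float]:
    """Variance components (a, b, c) for one biallelic locus.

    `counts` is an (r, 3) array of genotype counts [AA, AB, BB] per
    population.  Returns the among-population (a), among-individual-
    within-population (b) and within-individual (c) components of the
    standard diploid variance-component estimator.
    """
    n_i = counts.sum(axis=1).astype(float)
    keep = n_i > 0
    counts, n_i = counts[keep], n_i[keep]
    r = len(n_i)
    if r < 2:
        return np.nan, np.nan, np.nan
    p_i = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n_i)   # freq of B
    h_i = counts[:, 1] / n_i
    nbar = n_i.mean()
    if nbar <= 1:
        return np.nan, np.nan, np.nan
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    if pbar in (0.0, 1.0):
        return 0.0, 0.0, 0.0
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                             - (r - 1) / r * s2
                             - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                               - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return float(a), float(b), float(c)


def _ratios(a, b, c):
    abc = a + b + c
    fst = a / abc if abc else np.nan
    fit = (a + b) / abc if abc else np.nan
    fis = b / (b + c) if (b + c) else np.nan
    return fis, fit, fst


def weir_cockerham(gm: GenotypeMatrix, scheme: PopulationScheme,
                   loci: list[str] | None = None,
                   groups: list[str] | None = None) -> FStatResult:
    """Multi-locus Weir-Cockerham F-statistics over the named groups.

    Per-locus variance components are summed over loci and combined as
    Fst = Σa/Σ(a+b+c), Fit = Σ(a+b)/Σ(a+b+c), Fis = Σb/Σ(b+c), which
    satisfies (1-Fit) = (1-Fis)(1-Fst) exactly.  Standard errors come
    from a delete-one-locus jackknife.  Cells carrying a null allele
    (including null homozygotes) are excluded locus-wise, as are missing
    cells.
    """
    sub = gm.subset(loci=loci) if loci is not None else gm
    obs = observable_codes(sub.calls)
    group_names = groups if groups is not None else list(scheme.groups)
    germ = set(scheme.germplasm)
    pops = []
    for g in group_names:
        members = [a for a in scheme.groups[g] if a in germ]
        if len(members) < 2:
            raise ValueError(f"group {g} needs >= 2 germplasm accessions")
        pops.append([sub.acc_idx(a) for a in members])
    if len(pops) < 2:
        raise ValueError("need >= 2 groups")

    comp = np.full((sub.n_loci, 3), np.nan)
    for j in range(sub.n_loci):
        counts = np.zeros((len(pops), 3), dtype=int)
        for k, rows in enumerate(pops):
            col = obs[rows, j]
            counts[k, 0] = (col == AA).sum()
            counts[k, 1] = (col == AB).sum()
            counts[k, 2] = (col == BB).sum()
        comp[j] = _wc_components(counts)

    usable = ~np.isnan(comp).any(axis=1)
    poly = usable & (np.abs(comp).sum(axis=1) > 0)
    if not poly.any():
        raise ValueError("all loci monomorphic across the chosen groups")
    A, B, C = comp[poly, 0], comp[poly, 1], comp[poly, 2]
    fis, fit, fst = _ratios(A.sum(), B.sum(), C.sum())

    # delete-one jackknife over polymorphic loci
    L = poly.sum()
    if L > 1:
        jk = np.empty((L, 3))
        sa, sb, sc = A.sum(), B.sum(), C.sum()
        for l in range(L):
            jk[l] = _ratios(sa - A[l], sb - B[l], sc - C[l])
        fac = (L - 1) / L
        ses = np.sqrt(fac * ((jk - jk.mean(axis=0)) ** 2).sum(axis=0))
    else:
        ses = np.zeros(3)

    with np.errstate(invalid="ignore", divide="ignore"):
        abc = comp.sum(axis=1)
        fst_l = np.where(abc != 0, comp[:, 0] / abc, np.nan)
    per_locus = pd.DataFrame(
        {"a": comp[:, 0], "b": comp[:, 1], "c": comp[:, 2], "fst": fst_l},
        index=sub.locus_ids)
    return FStatResult(fis=fis, fit=fit, fst=fst,
                       fis_se=float(ses[0]), fit_se=float(ses[1]),
                       fst_se=float(ses[2]),
                       per_locus=per_locus, n_loci=int(L))
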