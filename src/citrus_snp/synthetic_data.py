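"""Synthetic stratified-gene-pool generator with ground-truth labels.

The generator reproduces the statistical structure the downstream
analyses assume, without any sequence-level detail:

* three to four ancestral taxa with strong allele-frequency divergence,
  drawn from a Balding-Nichols model (taxon frequency ~ Beta with mean
  p and variance F·p(1-p)), so realized between-taxon Fst tracks the
  configured divergence;
* clonally propagated interspecific hybrids with fixed heterozygosity
  (one gamete per parent taxon, then cloning);
* taxon-dependent null-allele frequencies at a null-prone subset of
  loci (high outside the discovery taxon);
* marker ascertainment through heterozygosity in a single hybrid
  discovery genotype;
* a biparental F1 progeny of a wide cross, with nulls inherited as
  ordinary alleles;
* optional duplicated (fixed-heterozygous-like) and low-call-rate loci,
  a haploid control accession, uniform missingness and a symmetric
  allele-swap genotyping-error model.

Loci are simulated unlinked; linkage disequilibrium among germplasm
arises from population structure alone.  An optional per-adjacent-pair
recombination fraction introduces linkage in the progeny only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd

from citrus_snp.genotype_io import (
    GenotypeMatrix, PopulationScheme, AA, AB, BB, A0, B0, NULL2, MISSING,
    observable_codes,
)

# Allele codes used internally by the generator.
_A, _B, _NULL = 0, 1, 2
# (allele, allele) -> call code, order-free.
_PAIR_TO_CALL = {
    (_A, _A): AA, (_A, _B): AB, (_B, _B): BB,
    (_A, _NULL): A0, (_B, _NULL): B0, (_NULL, _NULL): NULL2,
}


def _pair_code(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    lo = np.minimum(a1, a2)
    hi = np.maximum(a1, a2)
    lut = np.full((3, 3), -9, dtype=np.int8)
    for (x, y), c in _PAIR_TO_CALL.items():
        lut[x, y] = c
    return lut[lo, hi]


@dataclass
class TaxonSpec:
    name: str
    n_accessions: int
    divergence: float            # Balding-Nichols F in (0, 1)


@dataclass
class HybridSpec:
    """A named (possibly cloned) accession built from one gamete per
    parent taxon.  A 'hybrid' with both parents in the same taxon is
    simply a named individual of that taxon."""
    name: str
    parent_taxa: tuple[str, str]
    n_clones: int = 1


def _default_taxa() -> list[TaxonSpec]:
    return [
        TaxonSpec("reticulata_like", 12, 0.5),
        TaxonSpec("maxima_like", 10, 0.5),
        TaxonSpec("medica_like", 5, 0.5),
        TaxonSpec("papeda_like", 5, 0.5),
    ]


def _default_hybrids() -> list[HybridSpec]:
    return [
        HybridSpec("clementine_like", ("reticulata_like", "reticulata_like")),
        HybridSpec("chandler_like", ("maxima_like", "maxima_like")),
        HybridSpec("sweet_orange_like", ("reticulata_like", "maxima_like"), 2),
        HybridSpec("sour_orange_like", ("reticulata_like", "maxima_like"), 2),
        HybridSpec("lemon_like", ("medica_like", "reticulata_like"), 2),
        HybridSpec("lime_like", ("papeda_like", "medica_like"), 2),
    ]


def _default_null_rates() -> dict[str, float]:
    # Allele frequencies at null-prone loci, set so that HWE null-
    # homozygote frequencies land near the observed taxon profile
    # (~0.64 citron-like, ~0.61 pummelo-like, ~0.47 papeda-like, ~0.11
    # mandarin-like): nu^2 ≈ those values.
    return {"reticulata_like": 0.33, "maxima_like": 0.78,
            "medica_like": 0.80, "papeda_like": 0.69}


@dataclass
class SimulationConfig:
    n_loci: int = 600
    taxa: list[TaxonSpec] = field(default_factory=_default_taxa)
    hybrids: list[HybridSpec] = field(default_factory=_default_hybrids)
    null_allele_rate_by_taxon: dict[str, float] = field(
        default_factory=_default_null_rates)
    null_locus_fraction: float = 0.2
    duplicated_locus_fraction: float = 0.03
    low_quality_locus_fraction: float = 0.05
    low_quality_missing_rate: float = 0.5
    discovery_accession: str = "clementine_like"
    cross: tuple[str, str] = ("chandler_like", "clementine_like")
    progeny_size: int = 52
    progeny_recombination_fraction: float | None = None  # None: unlinked
    missing_rate: float = 0.02
    genotyping_error_rate: float = 0.0
    include_haploid_control: bool = True
    haploid_control_name: str = "haploid_control"
    seed: int = 42

    def __post_init__(self) -> None:
        for r in [self.null_locus_fraction, self.duplicated_locus_fraction,
                  self.low_quality_locus_fraction, self.missing_rate,
                  self.genotyping_error_rate,
                  *self.null_allele_rate_by_taxon.values()]:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        for t in self.taxa:
            if not 0.0 <= t.divergence < 1.0:
                raise ValueError("divergence must lie in [0, 1)")


@dataclass
class TruthRecord:
    locus_id: str
    true_category: str           # C1..C8
    null_prone: bool
    duplicated: bool
    low_quality: bool
    null_carriers: list[str]     # accessions holding >= 1 null allele
    ancestral_freq: float        # ancestral frequency of allele B
    taxon_freqs: dict[str, float]


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix    # with error + missingness applied
    truth_genotypes: GenotypeMatrix  # clean calls incl. explicit nulls
    truth: list[TruthRecord]
    scheme: PopulationScheme
    frequencies: pd.DataFrame    # loci × taxa, freq of allele B
    config: SimulationConfig


# ---------------------------------------------------------------------------

def simulate_ancestral_frequencies(cfg: SimulationConfig,
                                   rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-taxon allele-B frequencies under the Balding-Nichols
    divergence model: ancestral p ~ Uniform(0.05, 0.95), taxon frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (mean p, variance F·p(1-p)).  F -> 0
    collapses every taxon onto the ancestral frequency."""
    p = rng.uniform(0.05, 0.95, size=cfg.n_loci)
    cols = {"ancestral": p}
    for t in cfg.taxa:
        F = t.divergence
        if F <= 0:
            cols[t.name] = p.copy()
        else:
            k = (1.0 - F) / F
            cols[t.name] = rng.beta(p * k, (1.0 - p) * k)
    idx = [f"L{j:04d}" for j in range(cfg.n_loci)]
    return pd.DataFrame(cols, index=idx)


def _draw_taxon_alleles(freqs_B: np.ndarray, null_rate: np.ndarray,
                        size: tuple, rng: np.random.Generator) -> np.ndarray:
    """Draw alleles from a taxon's allele pool: null with probability
    `null_rate`, otherwise A/B by conditional frequency."""
    u = rng.random(size)
    v = rng.random(size)
    # per-locus vectors broadcast across accession/ploidy axes: the
    # locus axis is axis 1 for (n, L, 2) draws, axis 0 for (L,) gametes
    shape = [1] * len(size)
    shape[1 if len(size) == 3 else 0] = len(null_rate)
    nr = np.asarray(null_rate).reshape(shape)
    fB = np.asarray(freqs_B).reshape(shape)
    is_null = u < nr
    allele = np.where(v < fB, _B, _A)
    return np.where(is_null, _NULL, allele).astype(np.int8)


def simulate_accessions(freqs: pd.DataFrame, cfg: SimulationConfig,
                        rng: np.random.Generator):
    """Build germplasm + hybrid haplotypes.

    Returns (accession_ids, haplotypes (n_acc, n_loci, 2), taxon_of,
    null_prone mask).  Basic-taxon accessions are HWE draws within their
    taxon; hybrids take one gamete per parent taxon and clones are exact
    copies of the founder draw.
    """
    L = cfg.n_loci
    null_prone = rng.random(L) < cfg.null_locus_fraction
    taxon_null = {
        t.name: np.where(null_prone,
                         cfg.null_allele_rate_by_taxon.get(t.name, 0.0), 0.0)
        for t in cfg.taxa}
    taxon_pB = {t.name: freqs[t.name].to_numpy() for t in cfg.taxa}

    ids: list[str] = []
    haps: list[np.ndarray] = []
    taxon_of: dict[str, str] = {}

    for t in cfg.taxa:
        draws = _draw_taxon_alleles(taxon_pB[t.name], taxon_null[t.name],
                                    (t.n_accessions, L, 2), rng)
        for i in range(t.n_accessions):
            name = f"{t.name}_{i + 1:02d}"
            ids.append(name)
            haps.append(draws[i])
            taxon_of[name] = t.name

    for h in cfg.hybrids:
        g1 = _draw_taxon_alleles(taxon_pB[h.parent_taxa[0]],
                                 taxon_null[h.parent_taxa[0]], (L,), rng)
        g2 = _draw_taxon_alleles(taxon_pB[h.parent_taxa[1]],
                                 taxon_null[h.parent_taxa[1]], (L,), rng)
        founder = np.stack([g1, g2], axis=1)
        names = ([h.name] if h.n_clones == 1
                 else [f"{h.name}_{k + 1}" for k in range(h.n_clones)])
        for name in names:
            ids.append(name)
            haps.append(founder.copy())
            # clones carry the majority ancestry of their first parent
            taxon_of[name] = h.parent_taxa[0]

    return ids, np.stack(haps), taxon_of, null_prone


def simulate_progeny(haplotypes: np.ndarray, ids: list[str],
                     parentA: str, parentB: str, n: int,
                     rng: np.random.Generator,
                     recombination_fraction: float | None = None
                     ) -> np.ndarray:
    """F1 gametes: one allele per parent per locus.  With a
    recombination fraction, gametes follow the stored parental phase as
    a Markov chain along the locus order; otherwise loci are
    independent (r = 0.5).  Null alleles segregate as alleles."""
    ia, ib = ids.index(parentA), ids.index(parentB)
    L = haplotypes.shape[1]
    out = np.empty((n, L, 2), dtype=np.int8)
    for k in range(n):
        for slot, ip in ((0, ia), (1, ib)):
            if recombination_fraction is None:
                pick = rng.integers(0, 2, size=L)
            else:
                switch = rng.random(L) < recombination_fraction
                pick = np.zeros(L, dtype=np.int64)
                pick[0] = rng.integers(0, 2)
                for j in range(1, L):
                    pick[j] = pick[j - 1] ^ switch[j]
            out[k, :, slot] = haplotypes[ip, np.arange(L), pick]
    return out


def ascertain_markers(gm: GenotypeMatrix, discovery_accession: str,
                      mode: str = "CHet") -> list[str]:
    """Select loci through the discovery genotype, mirroring one-
    genotype SNP mining.

    ``CHet``: loci array-heterozygous in the discovery accession.
    ``CHom``: loci homozygous (called) in it but polymorphic genus-wide.
    ``genus_wide``: every locus polymorphic over all accessions.
    """
    obs = observable_codes(gm.calls)
    i = gm.acc_idx(discovery_accession)
    poly = np.array([
        len({c for c in obs[:, j] if c in (AA, AB, BB)}) >= 2
        for j in range(gm.n_loci)])
    disc = obs[i]
    if mode == "CHet":
        keep = disc == AB
    elif mode == "CHom":
        keep = np.isin(disc, (AA, BB)) & poly
    elif mode == "genus_wide":
        keep = poly
    else:
        raise ValueError(f"unknown ascertainment mode {mode!r}")
    return [l for l, k in zip(gm.locus_ids, keep) if k]


# ---------------------------------------------------------------------------

def _truth_category(j: int, calls_true: np.ndarray, ids: list[str],
                    cfg: SimulationConfig, duplicated: np.ndarray,
                    low_quality: np.ndarray,
                    germplasm_rows: list[int]) -> str:
    if low_quality[j]:
        return "C1"
    if duplicated[j]:
        return "C7"
    disc = int(calls_true[ids.index(cfg.discovery_accession), j])
    other = int(calls_true[ids.index(cfg.cross[0]), j])
    col = calls_true[germplasm_rows, j]
    any_null = bool(np.isin(col, (A0, B0, NULL2)).any()
                    or other in (A0, B0, NULL2))
    if disc == AB:
        return "C3" if any_null else "C2"
    if disc in (A0, B0):
        return "C4"
    # no SNP segregation from the discovery genotype
    called = col[np.isin(col, (AA, AB, BB, A0, B0))]
    obs_called = observable_codes(called) if called.size else called
    has_A = np.isin(obs_called, (AA, AB)).any()
    has_B = np.isin(obs_called, (AB, BB)).any()
    snp_poly = (has_A and has_B) or (AB in obs_called)
    if snp_poly:
        return "C5"
    if (col == NULL2).any() and called.size:
        return "C6"
    return "C8"


def simulate_dataset(cfg: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulatedDataset:
    """Run the full generator: frequencies -> accessions -> progeny ->
    duplicated/low-quality loci -> error and missingness.  Fixed seed
    gives byte-identical output."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    freqs = simulate_ancestral_frequencies(cfg, rng)
    locus_ids = list(freqs.index)
    ids, haps, taxon_of, null_prone = simulate_accessions(freqs, cfg, rng)

    prog = simulate_progeny(haps, ids, cfg.cross[0], cfg.cross[1],
                            cfg.progeny_size, rng,
                            cfg.progeny_recombination_fraction)
    prog_ids = [f"progeny_{k + 1:02d}" for k in range(cfg.progeny_size)]
    all_ids = ids + prog_ids
    all_haps = np.concatenate([haps, prog], axis=0)

    L = cfg.n_loci
    duplicated = rng.random(L) < cfg.duplicated_locus_fraction
    low_quality = rng.random(L) < cfg.low_quality_locus_fraction
    duplicated &= ~low_quality           # call-rate failure masks all else

    calls_true = _pair_code(all_haps[:, :, 0], all_haps[:, :, 1])
    calls_true[:, duplicated] = AB       # fixed heterozygous-like signal

    if cfg.include_haploid_control:
        hap_gamete = _draw_taxon_alleles(
            freqs[taxon_of[cfg.discovery_accession]].to_numpy(),
            np.zeros(L), (L,), rng)
        hap_calls = _pair_code(hap_gamete, hap_gamete)
        hap_calls[duplicated] = AB       # duplication shows het-like even haploid
        calls_true = np.vstack([calls_true, hap_calls[None, :]])
        all_ids = all_ids + [cfg.haploid_control_name]

    germplasm_rows = [k for k, a in enumerate(all_ids)
                      if a in ids]       # incl. parents, excl. progeny/haploid
    truth = []
    for j, lid in enumerate(locus_ids):
        carriers = [all_ids[k] for k in range(len(ids))
                    if calls_true[k, j] in (A0, B0, NULL2)]
        truth.append(TruthRecord(
            locus_id=lid,
            true_category=_truth_category(j, calls_true, all_ids, cfg,
                                          duplicated, low_quality,
                                          germplasm_rows),
            null_prone=bool(null_prone[j]), duplicated=bool(duplicated[j]),
            low_quality=bool(low_quality[j]), null_carriers=carriers,
            ancestral_freq=float(freqs["ancestral"].iloc[j]),
            taxon_freqs={t.name: float(freqs[t.name].iloc[j])
                         for t in cfg.taxa}))

    # genotyping error: symmetric swap of one allele A<->B per hit cell
    emitted = calls_true.copy()
    if cfg.genotyping_error_rate > 0:
        hit = rng.random(emitted.shape) < cfg.genotyping_error_rate
        swap_first = rng.random(emitted.shape) < 0.5
        flip_lut_first = np.array([BB, AB, BB, B0, B0, NULL2], dtype=np.int8)
        flip_lut_second = np.array([AA, AA, AB, A0, A0, NULL2], dtype=np.int8)
        # flipping AB gives AA or BB depending on which allele swaps
        flip_lut_first[AB] = BB
        flip_lut_second[AB] = AA
        sel = hit & (emitted >= 0)
        emitted[sel & swap_first] = flip_lut_first[emitted[sel & swap_first]]
        emitted[sel & ~swap_first] = flip_lut_second[emitted[sel & ~swap_first]]

    # missingness: uniform, elevated at low-quality loci
    miss_p = np.full(L, cfg.missing_rate)
    miss_p[low_quality] = cfg.low_quality_missing_rate
    miss = rng.random(emitted.shape) < miss_p[None, :]
    emitted[miss] = MISSING

    gm = GenotypeMatrix(all_ids, locus_ids, emitted)
    gm_true = GenotypeMatrix(list(all_ids), locus_ids, calls_true)

    groups: dict[str, list[str]] = {t.name: [] for t in cfg.taxa}
    hybrid_group: dict[str, str] = {}
    for h in cfg.hybrids:
        base = h.name
        gname = (base if base not in (cfg.discovery_accession, cfg.cross[0])
                 else taxon_of[base])
        names = ([base] if h.n_clones == 1
                 else [f"{base}_{k + 1}" for k in range(h.n_clones)])
        for nm in names:
            hybrid_group[nm] = gname
    for a in ids:
        if a in hybrid_group:
            groups.setdefault(hybrid_group[a], []).append(a)
        else:
            groups[taxon_of[a]].append(a)
    roles = {a: "germplasm" for a in ids}
    roles[cfg.cross[0]] = "parent_female"
    roles[cfg.cross[1]] = "parent_male"
    for p in prog_ids:
        roles[p] = "progeny"
    if cfg.include_haploid_control:
        roles[cfg.haploid_control_name] = "germplasm"
    scheme = PopulationScheme(groups=groups, roles=roles)

    return SimulatedDataset(genotypes=gm, truth_genotypes=gm_true,
                            truth=truth, scheme=scheme, frequencies=freqs,
                            config=cfg)


def truth_to_json(ds: SimulatedDataset, path) -> None:
    payload = {
        "config": {
            **{k: v for k, v in asdict(ds.config).items()
               if k not in ("taxa", "hybrids")},
            "taxa": [asdict(t) for t in ds.config.taxa],
            "hybrids": [asdict(h) for h in ds.config.hybrids],
        },
        "truth": [asdict(t) for t in ds.truth],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
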