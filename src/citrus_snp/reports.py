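"""Small worked-count summaries: validation concordance, mined-SNP
composition and per-kilobase SNP density.

These operate on plain counts (number of genotype×SNP comparisons in
agreement, numbers of transitions/transversions/InDels among mined
variants, SNPs found per kilobase sequenced) and report percentages at
printed precision with half-up rounding.
"""

from __future__ import annotations

from citrus_snp.genotype_io import round_half_up


def concordance_percent(n_agree: int, n_total: int, decimals: int = 1) -> float:
    """Percent of genotype×SNP validation comparisons in agreement."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_agree <= n_total:
        raise ValueError("n_agree must lie in [0, n_total]")
    return round_half_up(100.0 * n_agree / n_total, decimals)


def composition_percent(counts: dict[str, int],
                        total: int | None = None,
                        decimals: int = 1) -> dict[str, float]:
    """Percentage composition of variant classes (e.g. transition /
    transversion / InDel) out of `total` mined variants (defaults to the
    sum of the counts)."""
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round_half_up(100.0 * v / total, decimals)
            for k, v in counts.items()}


def snp_density_per_kb(n_snps: int, kb_sequenced: float,
                       decimals: int = 1) -> float:
    """SNPs per kilobase of sequence screened."""
    if kb_sequenced <= 0:
        raise ValueError("kb_sequenced must be positive")
    return round_half_up(n_snps / kb_sequenced, decimals)
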