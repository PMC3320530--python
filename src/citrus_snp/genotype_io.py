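"""Genotype data model and tabular / VCF input-output.

Diploid biallelic calls live on the alphabet {A, B, 0}, where ``0`` is a
null allele (an allele giving no array signal: a deletion or a
primer-site polymorphism).  The null homozygote ``00`` is a *called*
state — a consistent no-signal cluster — and is distinct from the
missing sentinel ``--`` (assay failure).  Calls are stored as unordered
allele pairs; the array-observable collapse of null heterozygotes
(``A0`` looks like ``AA``) is applied only inside the classifier, never
in storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
import json

import numpy as np
import pandas as pd

# Integer codes for the seven cell states.  MISSING is -1 so that
# ``calls >= 0`` masks typed cells.
AA, AB, BB, A0, B0, NULL2, MISSING = 0, 1, 2, 3, 4, 5, -1

CODE_TO_TOKEN = {AA: "AA", AB: "AB", BB: "BB", A0: "A0", B0: "B0",
                 NULL2: "00", MISSING: "--"}
# Canonical ordering on construction: BA ≡ AB, 0A ≡ A0, 0B ≡ B0.
TOKEN_TO_CODE = {
    "AA": AA, "AB": AB, "BA": AB, "BB": BB,
    "A0": A0, "0A": A0, "B0": B0, "0B": B0,
    "00": NULL2, "--": MISSING,
}

# Allele multiset per code, as counts of (A, B, 0).
ALLELE_COUNTS = np.zeros((6, 3), dtype=np.int8)
ALLELE_COUNTS[AA] = (2, 0, 0)
ALLELE_COUNTS[AB] = (1, 1, 0)
ALLELE_COUNTS[BB] = (0, 2, 0)
ALLELE_COUNTS[A0] = (1, 0, 1)
ALLELE_COUNTS[B0] = (0, 1, 1)
ALLELE_COUNTS[NULL2] = (0, 0, 2)

#: Array-observable state of each stored state: null heterozygotes are
#: indistinguishable from the expected homozygotes on the platform.
OBSERVABLE = {AA: AA, AB: AB, BB: BB, A0: AA, B0: BB, NULL2: NULL2,
              MISSING: MISSING}
_OBS_LUT = np.array([AA, AB, BB, AA, BB, NULL2], dtype=np.int8)


def observable_codes(calls: np.ndarray) -> np.ndarray:
    """Collapse null heterozygotes to their homozygous-looking state."""
    out = calls.copy()
    typed = calls >= 0
    out[typed] = _OBS_LUT[calls[typed]]
    return out


class GenotypeFormatError(ValueError):
    """Malformed genotype table (ragged rows, unknown tokens, dup ids)."""


@dataclass
class GenotypeMatrix:
    """Accessions × loci grid of diploid calls.

    Parameters
    ----------
    accession_ids, locus_ids
        Unique, ordered identifiers.
    calls
        ``int8`` array of shape ``(n_accessions, n_loci)`` holding the
        cell codes above.
    """

    accession_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_acc, n_loc = self.calls.shape
        if n_acc != len(self.accession_ids) or n_loc != len(self.locus_ids):
            raise ValueError("calls shape does not match id lists")
        if len(set(self.accession_ids)) != n_acc:
            raise GenotypeFormatError("duplicate accession ids")
        if len(set(self.locus_ids)) != n_loc:
            raise GenotypeFormatError("duplicate locus ids")
        self._acc_index = {a: i for i, a in enumerate(self.accession_ids)}
        self._loc_index = {l: j for j, l in enumerate(self.locus_ids)}

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def acc_idx(self, accession_id: str) -> int:
        return self._acc_index[accession_id]

    def loc_idx(self, locus_id: str) -> int:
        return self._loc_index[locus_id]

    def missing_fraction(self) -> np.ndarray:
        """Per-locus proportion of MISSING cells, in [0, 1]."""
        return (self.calls == MISSING).mean(axis=0)

    def observable(self) -> "GenotypeMatrix":
        """Array view: A0→AA, B0→BB; 00 and MISSING unchanged."""
        return GenotypeMatrix(list(self.accession_ids), list(self.locus_ids),
                              observable_codes(self.calls))

    def subset(self, accessions=None, loci=None) -> "GenotypeMatrix":
        rows = (list(range(self.n_accessions)) if accessions is None
                else [self._acc_index[a] for a in accessions])
        cols = (list(range(self.n_loci)) if loci is None
                else [self._loc_index[l] for l in loci])
        return GenotypeMatrix(
            [self.accession_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.calls[np.ix_(rows, cols)],
        )

    def dosage(self, allele: str = "B") -> np.ndarray:
        """Float matrix of per-cell counts of `allele` (A, B or 0);
        MISSING cells become NaN."""
        col = {"A": 0, "B": 1, "0": 2}[allele]
        out = np.full(self.calls.shape, np.nan)
        typed = self.calls >= 0
        out[typed] = ALLELE_COUNTS[self.calls[typed], col]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        tokens = np.vectorize(CODE_TO_TOKEN.get)(self.calls)
        return pd.DataFrame(tokens, index=self.accession_ids,
                            columns=self.locus_ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, GenotypeMatrix)
                and self.accession_ids == other.accession_ids
                and self.locus_ids == other.locus_ids
                and np.array_equal(self.calls, other.calls))


@dataclass
class MarkerRecord:
    """Per-locus metadata, assigned category and valid-set membership.

    Categories: C1 clustering/call-rate failure; C2 expected segregation
    of the heterozygous discovery genotype; C3 unexpected segregation
    revealing a null allele in the other parent or germplasm; C4
    heterozygous null in the discovery genotype itself; C5 germplasm SNP
    polymorphism without segregation; C6 null-allele presence/absence
    polymorphism only; C7 fixed heterozygous-like pattern (suspected
    duplicated locus); C8 monomorphic.
    """

    locus_id: str
    source: str = "BES"                      # BES | candidate_gene
    substitution_type: str = "transition"    # transition | transversion
    category: str = "unassigned"             # C1..C8 | unassigned
    valid_set: str = "excluded"              # WONA | WNA | excluded
    clementine_state: str = "unknown"        # het | hom | null_het | unknown
    diagnostics: dict = field(default_factory=dict)

    _WONA_CATS = {"C2", "C5"}
    _WNA_CATS = {"C3", "C4", "C6"}

    def __post_init__(self) -> None:
        if self.valid_set == "WONA" and self.category not in self._WONA_CATS:
            raise ValueError(
                f"{self.locus_id}: WONA requires category C2/C5, "
                f"got {self.category}")
        if self.valid_set == "WNA" and self.category not in self._WNA_CATS:
            raise ValueError(
                f"{self.locus_id}: WNA requires category C3/C4/C6, "
                f"got {self.category}")


ROLES = {"germplasm", "parent_female", "parent_male", "progeny"}


@dataclass
class PopulationScheme:
    """Accession → taxon-group mapping plus analysis roles."""

    groups: dict[str, list[str]]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values()} - ROLES
        if bad:
            raise ValueError(f"unknown roles: {sorted(bad)}")
        seen: dict[str, str] = {}
        for g, members in self.groups.items():
            for a in members:
                if a in seen:
                    raise ValueError(
                        f"accession {a} in both {seen[a]} and {g}")
                seen[a] = g

    def group_of(self, accession: str) -> str | None:
        for g, members in self.groups.items():
            if accession in members:
                return g
        return None

    def accessions_with_role(self, role: str) -> list[str]:
        return [a for a, r in self.roles.items() if r == role]

    @property
    def germplasm(self) -> list[str]:
        return self.accessions_with_role("germplasm")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"groups": self.groups, "roles": self.roles}, indent=1))

    @classmethod
    def from_json(cls, path) -> "PopulationScheme":
        d = json.loads(Path(path).read_text())
        return cls(groups=d["groups"], roles=d["roles"])


# ---------------------------------------------------------------------------
# Tabular I/O

def read_genotype_table(path, sep: str = "\t") -> GenotypeMatrix:
    """Read a genotype table: header row of locus ids, first column the
    accession id, cells from {AA, AB, BB, A0, B0, 00, --} (allele order
    within a cell is canonicalized).

    Raises
    ------
    GenotypeFormatError
        On ragged rows, unknown cell tokens or duplicate ids.
    """
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if not lines:
        raise GenotypeFormatError("empty genotype table")
    header = lines[0].split(sep)
    locus_ids = header[1:]
    width = len(header)
    accession_ids: list[str] = []
    rows: list[list[int]] = []
    for k, ln in enumerate(lines[1:], start=2):
        fields = ln.split(sep)
        if len(fields) != width:
            raise GenotypeFormatError(
                f"line {k}: expected {width} fields, found {len(fields)}")
        accession_ids.append(fields[0])
        row = []
        for tok, locus in zip(fields[1:], locus_ids):
            try:
                row.append(TOKEN_TO_CODE[tok])
            except KeyError:
                raise GenotypeFormatError(
                    f"line {k}, locus {locus}: unknown token {tok!r}")
        rows.append(row)
    return GenotypeMatrix(accession_ids, locus_ids,
                          np.array(rows, dtype=np.int8).reshape(
                              len(accession_ids), len(locus_ids)))


def write_genotype_table(gm: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the TSV dialect read by :func:`read_genotype_table`."""
    with open(path, "w") as fh:
        fh.write(sep.join(["accession"] + list(gm.locus_ids)) + "\n")
        for i, acc in enumerate(gm.accession_ids):
            toks = [CODE_TO_TOKEN[int(c)] for c in gm.calls[i]]
            fh.write(sep.join([acc] + toks) + "\n")


# ---------------------------------------------------------------------------
# VCF export

def write_vcf(gm: GenotypeMatrix, markers: list[MarkerRecord] | None,
              path, null_policy: str = "missing") -> None:
    """Export a minimal VCF 4.2 file.

    VCF has no native null-allele concept.  With ``null_policy=
    "missing"`` (default) any call carrying a null allele is exported as
    ``./.`` and the site is flagged ``NULLALLELE``; the lossless record
    stays in the TSV dialect.  With ``null_policy="symbolic"`` the null
    allele is a symbolic ``<NULL>`` ALT (index 2).

    Loci get placeholder coordinates (single contig, 1-based rank) and
    the letter alleles REF=A, ALT=C standing in for the unspecified
    biallelic substitution.
    """
    if null_policy not in {"missing", "symbolic"}:
        raise ValueError(f"unknown null_policy {null_policy!r}")
    by_id = {m.locus_id: m for m in (markers or [])}
    gt_map = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}
    if null_policy == "symbolic":
        gt_map.update({A0: "0/2", B0: "1/2", NULL2: "2/2"})
    else:
        gt_map.update({A0: "./.", B0: "./.", NULL2: "./."})
    alt = "C,<NULL>" if null_policy == "symbolic" else "C"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=synthetic,length=%d>\n" % max(gm.n_loci, 1))
        fh.write('##INFO=<ID=NULLALLELE,Number=0,Type=Flag,'
                 'Description="Site segregates a null allele">\n')
        fh.write('##INFO=<ID=CATEGORY,Number=1,Type=String,'
                 'Description="Marker category C1-C8">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write(f"##null_allele_policy={null_policy}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        for j, locus in enumerate(gm.locus_ids):
            col = gm.calls[:, j]
            has_null = bool(np.isin(col, (A0, B0, NULL2)).any())
            info = []
            if has_null:
                info.append("NULLALLELE")
            rec = by_id.get(locus)
            if rec is not None and rec.category != "unassigned":
                info.append(f"CATEGORY={rec.category}")
            gts = "\t".join(gt_map[int(c)] for c in col)
            fh.write(f"synthetic\t{j + 1}\t{locus}\tA\t{alt}\t.\t.\t"
                     f"{';'.join(info) or '.'}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Selection / transferability summaries

def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (printed-precision convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SelectionSummary:
    n_wona: int
    n_wna: int
    n_excluded: int
    transferability_percent: float          # WONA / (WONA + WNA), all loci
    transferability_percent_bes: float | None  # restricted to source=BES


def summarize_selection(markers: list[MarkerRecord]) -> SelectionSummary:
    """Count WONA / WNA / excluded loci and the transferability rate.

    Transferability is the fraction of consistently genotyped loci that
    carry no null allele, WONA/(WONA+WNA), reported as a half-up
    percentage with one decimal; it is also computed restricted to loci
    mined from BAC-end sequences (source ``BES``), the discovery
    substrate whose transfer across the genus is at stake.
    """
    if not markers:
        raise ValueError("empty marker list")
    n_wona = sum(m.valid_set == "WONA" for m in markers)
    n_wna = sum(m.valid_set == "WNA" for m in markers)
    n_excluded = len(markers) - n_wona - n_wna
    if n_wona + n_wna == 0:
        raise ValueError("no valid (WONA/WNA) markers to summarize")
    overall = round_half_up(100.0 * n_wona / (n_wona + n_wna))
    bes = [m for m in markers if m.source == "BES"
           and m.valid_set in ("WONA", "WNA")]
    bes_pct = None
    if bes:
        bes_wona = sum(m.valid_set == "WONA" for m in bes)
        bes_pct = round_half_up(100.0 * bes_wona / len(bes))
    return SelectionSummary(n_wona, n_wna, n_excluded, overall, bes_pct)
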