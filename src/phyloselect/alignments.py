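"""Alignment containers and standard-format I/O.

Codon alignments are in-frame CDS alignments over {A,C,G,T,-,N}; protein
alignments use the 20-letter alphabet plus {-, X}.  FASTA and PHYLIP
(sequential or interleaved, relaxed names) are read and written through
Biopython.  Coordinates are 0-based half-open internally; every report and
feature file uses 1-based positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gencode import translate_codon


class AlignmentFormatError(ValueError):
    pass


class AlignmentValidationError(ValueError):
    pass


@dataclass
class ProteinAlignment:
    """Rectangular amino-acid alignment."""

    taxa: list[str]
    rows: list[str]
    id: str = ""

    def __post_init__(self) -> None:
        self.rows = [r.upper() for r in self.rows]
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentValidationError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            bad = self.taxa[[len(r) for r in self.rows].index(max(
                (len(r) for r in self.rows)))]
            raise AlignmentFormatError(
                f"ragged alignment: row lengths differ (see taxon {bad!r})")

    @property
    def length_aa(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def column(self, i: int) -> str:
        return "".join(r[i] for r in self.rows)

    def select_columns(self, keep: list[int]) -> "ProteinAlignment":
        rows = ["".join(r[i] for i in keep) for r in self.rows]
        return ProteinAlignment(list(self.taxa), rows, id=self.id)

    def reorder(self, taxa: list[str]) -> "ProteinAlignment":
        return ProteinAlignment(list(taxa), [self.row(t) for t in taxa], self.id)


@dataclass
class CodonAlignment:
    """Rectangular in-frame codon alignment (no internal stop codons)."""

    taxa: list[str]
    rows: list[str]
    id: str = ""

    def __post_init__(self) -> None:
        self.rows = [r.upper() for r in self.rows]
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentValidationError("duplicate taxon labels")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentFormatError("ragged alignment: row lengths differ")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise AlignmentValidationError(
                f"alignment length {len(self.rows[0])} not divisible by 3")
        for taxon, row in zip(self.taxa, self.rows):
            for i in range(0, len(row), 3):
                if translate_codon(row[i:i + 3]) == "*":
                    raise AlignmentValidationError(
                        f"in-frame stop codon {row[i:i+3]} in taxon {taxon!r} "
                        f"at nt position {i + 1} (1-based)")

    @property
    def length_nt(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_codons(self) -> int:
        return self.length_nt // 3

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def codon(self, taxon_idx: int, col: int) -> str:
        return self.rows[taxon_idx][3 * col:3 * col + 3]

    def select_codon_columns(self, keep: list[int]) -> "CodonAlignment":
        rows = ["".join(r[3 * i:3 * i + 3] for i in keep) for r in self.rows]
        return CodonAlignment(list(self.taxa), rows, id=self.id)


Alignment = ProteinAlignment | CodonAlignment


def _parse_records(path: str, fmt: str) -> list[tuple[str, str]]:
    if fmt == "fasta":
        recs = list(SeqIO.parse(path, "fasta"))
        if not recs:
            raise AlignmentFormatError(f"no FASTA records in {path}")
        return [(r.id, str(r.seq)) for r in recs]
    if fmt == "phylip":
        last_err: Exception | None = None
        for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                msa = AlignIO.read(path, dialect)
                return [(r.id, str(r.seq)) for r in msa]
            except Exception as err:  # try the next dialect
                last_err = err
        raise AlignmentFormatError(f"could not parse {path} as PHYLIP: {last_err}")
    raise ValueError(f"unknown format {fmt!r} (use 'fasta' or 'phylip')")


def read_alignment(path: str, format: str = "fasta",
                   level: str = "protein") -> Alignment:
    """Read an alignment file; level selects the codon or protein container."""
    pairs = _parse_records(path, format)
    taxa = [t for t, _ in pairs]
    rows = [s for _, s in pairs]
    lengths = [len(r) for r in rows]
    if len(set(lengths)) > 1:
        bad = taxa[int(np.argmax(np.asarray(lengths) != lengths[0]))]
        raise AlignmentFormatError(
            f"ragged rows in {path}: taxon {bad!r} has length "
            f"{len(rows[taxa.index(bad)])}, expected {lengths[0]}")
    cls = CodonAlignment if level == "codon" else ProteinAlignment
    return cls(taxa, rows, id=path)


def write_alignment(aln: Alignment, path: str, format: str = "fasta") -> None:
    recs = [SeqRecord(Seq(r), id=t, description="")
            for t, r in zip(aln.taxa, aln.rows)]
    if format == "fasta":
        SeqIO.write(recs, path, "fasta")
    elif format == "phylip":
        AlignIO.write(MultipleSeqAlignment(recs), path, "phylip-relaxed")
    else:
        raise ValueError(f"unknown format {format!r}")


def translate(aln: CodonAlignment, table_id: int = 1) -> ProteinAlignment:
    """Column i of the output corresponds to codons [3i, 3i+3)."""
    rows = []
    for row in aln.rows:
        rows.append("".join(translate_codon(row[i:i + 3], table_id)
                            for i in range(0, len(row), 3)))
    return ProteinAlignment(list(aln.taxa), rows, id=aln.id)


def backtranslate(prot_aln: ProteinAlignment, cds: dict[str, str],
                  table_id: int = 1) -> CodonAlignment:
    """Expand a protein alignment back to codons using each taxon's ungapped CDS."""
    rows = []
    for taxon in prot_aln.taxa:
        if taxon not in cds:
            raise AlignmentValidationError(f"no CDS supplied for taxon {taxon!r}")
        seq = cds[taxon].upper().replace("-", "")
        prot = prot_aln.row(taxon)
        out, k = [], 0
        for res_i, aa in enumerate(prot, start=1):
            if aa == "-":
                out.append("---")
                continue
            codon = seq[3 * k:3 * k + 3]
            if len(codon) < 3:
                raise AlignmentValidationError(
                    f"CDS for {taxon!r} too short at residue {res_i}")
            trans = translate_codon(codon, table_id)
            if trans != aa and not (aa == "X" and trans in "X*"):
                raise AlignmentValidationError(
                    f"translation mismatch for taxon {taxon!r} at residue "
                    f"{res_i}: alignment has {aa!r}, CDS codon {codon} "
                    f"encodes {trans!r}")
            out.append(codon)
            k += 1
        if 3 * k < len(seq):
            raise AlignmentValidationError(
                f"CDS for {taxon!r} has {len(seq) - 3 * k} trailing nt beyond "
                "the aligned protein")
        rows.append("".join(out))
    return CodonAlignment(list(prot_aln.taxa), rows, id=prot_aln.id)


@dataclass
class AlignmentQualityReport:
    observed_score: float
    null_mean: float
    null_sd: float
    z_score: float
    n_shuffles: int
    seed: int
    undefined: bool = False


_GAP_PENALTY = -8.0
_BLOSUM62 = None


def _blosum62():
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return _BLOSUM62


def _sum_of_pairs(cols: np.ndarray, score: np.ndarray) -> float:
    """cols: (n_taxa, length) integer-coded (-1 gap/unknown)."""
    n = cols.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = cols[i], cols[j]
            both = (a >= 0) & (b >= 0)
            one = (a >= 0) ^ (b >= 0)
            total += score[a[both], b[both]].sum() + _GAP_PENALTY * one.sum()
    return float(total)


def alignment_z_score(aln: ProteinAlignment, n_shuffles: int = 200,
                      seed: int = 0) -> AlignmentQualityReport:
    """Alignment-quality randomization test.

    The observed sum-of-pairs BLOSUM62 score (gap-vs-residue scored by a fixed
    penalty, gap-vs-gap 0) is compared to a null built by shuffling each row's
    residues independently while freezing its gap positions, so the null keeps
    the alignment's gap architecture and destroys only residue order.
    """
    if aln.n_taxa < 2:
        raise AlignmentValidationError("need >= 2 taxa for the z-score test")
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    mat = _blosum62()
    alpha = mat.alphabet
    lut = {aa: i for i, aa in enumerate(alpha)}
    score = np.array(mat)
    coded = np.array([[lut.get(c, -1) if c not in "-" else -1 for c in row]
                      for row in aln.rows], dtype=int)
    observed = _sum_of_pairs(coded, score)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    residue_pos = [np.flatnonzero(coded[i] >= 0) for i in range(aln.n_taxa)]
    work = coded.copy()
    for b in range(n_shuffles):
        for i, pos in enumerate(residue_pos):
            work[i, pos] = coded[i, pos][rng.permutation(pos.size)]
        null[b] = _sum_of_pairs(work, score)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0.0:
        return AlignmentQualityReport(observed, mean, sd, float("nan"),
                                      n_shuffles, seed, undefined=True)
    return AlignmentQualityReport(observed, mean, sd, (observed - mean) / sd,
                                  n_shuffles, seed)


def read_feature_table(path: str) -> pd.DataFrame:
    """Feature TSV with header ``position<TAB>label<TAB>category`` (1-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"position", "label", "category"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"feature table {path} must have columns {sorted(required)}")
    df["position"] = df["position"].astype(int)
    return df


def residue_counts(aln: ProteinAlignment) -> np.ndarray:
    """Pooled counts over the 20 amino acids (gaps/X excluded)."""
    from .substmodels import aa_index
    counts = np.zeros(20)
    for row in aln.rows:
        for c in row:
            i = aa_index(c)
            if i is not None:
                counts[i] += 1
    return counts
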