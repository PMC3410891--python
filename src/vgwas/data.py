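"""Data containers and I/O for inbred-line association scans.

Genotypes are biallelic markers typed on fully homozygous accessions, so
each call is 0 or 2 copies of the ``allele_b`` allele; heterozygous calls
only arise as genotyping noise and are handled by a read-time policy.
Phenotypes are one numeric value per accession per trait (no replicate
structure), held as a pandas DataFrame with NaN for missing.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Out-of-band sentinel for a missing genotype call in the int8 call matrix.
#: Valid calls are 0 and 2 (copies of allele_b); MISSING is never a genotype.
MISSING = np.int8(-1)

_VALID_CALLS = frozenset({0, 2})


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class GenotypeMatrix:
    """Markers x accessions homozygous-call matrix with its marker map.

    Parameters
    ----------
    marker_ids : array of str
        Unique marker identifiers.
    chrom : array of str
        Chromosome label per marker.
    pos : array of int
        1-based physical position per marker (inclusive coordinates, as in
        VCF).
    allele_a, allele_b : array of str
        Single-character allele labels; ``calls`` counts copies of
        ``allele_b``.
    calls : int8 ndarray, shape (n_markers, n_accessions)
        Entries in {0, 2, MISSING}.
    accession_ids : array of str
        Unique accession identifiers (column order of ``calls``).
    """

    marker_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    calls: np.ndarray
    accession_ids: np.ndarray
    _marker_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)
        self.accession_ids = np.asarray(self.accession_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)

        n_m, n_a = self.calls.shape
        if len(self.marker_ids) != n_m or len(self.accession_ids) != n_a:
            raise DataError("call matrix shape does not match id lists")
        if len(set(self.marker_ids)) != n_m:
            raise DataError("duplicate marker id")
        if len(set(self.accession_ids)) != n_a:
            raise DataError("duplicate accession id")
        if np.any(self.pos <= 0):
            raise DataError("marker positions must be strictly positive (1-based)")
        bad = ~np.isin(self.calls, [0, 2, MISSING])
        if bad.any():
            raise DataError("calls must be 0, 2 or MISSING")
        self._marker_index = {m: i for i, m in enumerate(self.marker_ids)}

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_accessions(self) -> int:
        return self.calls.shape[1]

    def marker_row(self, marker_id: str) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker id: {marker_id!r}") from None

    def accession_indexer(self, accession_ids) -> np.ndarray:
        """Column indices for a subset of accessions, in the given order."""
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in accession_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown accession id: {exc.args[0]!r}") from None

    def to_tsv(self, path) -> None:
        """Write the genotype TSV dialect (header: marker_id chrom pos
        allele_a allele_b <acc...>; cells 0/2/NA)."""
        with open(path, "w") as fh:
            header = ["marker_id", "chrom", "pos", "allele_a", "allele_b"]
            fh.write("\t".join(header + list(self.accession_ids)) + "\n")
            for i in range(self.n_markers):
                cells = [
                    "NA" if c == MISSING else str(int(c)) for c in self.calls[i]
                ]
                row = [
                    str(self.marker_ids[i]),
                    str(self.chrom[i]),
                    str(self.pos[i]),
                    str(self.allele_a[i]),
                    str(self.allele_b[i]),
                ]
                fh.write("\t".join(row + cells) + "\n")


@dataclass
class PhenotypeTable:
    """Accession x trait numeric matrix; NaN marks a missing measurement."""

    frame: pd.DataFrame  # index: accession_id, columns: trait names, float

    def __post_init__(self):
        self.frame = self.frame.astype(float)
        if self.frame.index.has_duplicates:
            raise DataError("duplicate accession id in phenotype table")
        empty = self.frame.columns[self.frame.notna().sum(axis=0) == 0]
        if len(empty):
            raise DataError(f"trait(s) with no non-missing value: {list(empty)}")

    @property
    def accession_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy(dtype=object)

    @property
    def trait_names(self) -> list:
        return list(self.frame.columns)

    def trait(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            raise KeyError(f"unknown trait: {name!r}")
        return self.frame[name]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", na_rep="NA", index_label="accession_id")


@dataclass
class GenotypeGroups:
    """Per-accession genotype grouping at one marker.

    ``group_index`` holds the raw call (0, 2 or MISSING) per accession of the
    analyzed subset; ``n_low``/``n_high`` count the 0- and 2-coded genotype
    classes among non-missing calls.
    """

    group_index: np.ndarray
    n_low: int
    n_high: int

    @property
    def n_per_group(self) -> tuple:
        return tuple(n for n in (self.n_low, self.n_high) if n > 0)

    @property
    def K(self) -> int:
        return int(self.n_low > 0) + int(self.n_high > 0)

    @property
    def N(self) -> int:
        return self.n_low + self.n_high

    def masks(self):
        """Boolean masks (low_mask, high_mask) over ``group_index``."""
        return self.group_index == 0, self.group_index == 2


# ---------------------------------------------------------------------------
# readers / writers


def _parse_genotype_tsv(path) -> GenotypeMatrix:
    marker_ids, chroms, poss, aas, abs_, rows = [], [], [], [], [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:5] != ["marker_id", "chrom", "pos", "allele_a", "allele_b"]:
            raise DataError(f"{path}: bad genotype TSV header")
        accessions = header[5:]
        n_acc = len(accessions)
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5 + n_acc:
                raise DataError(f"{path}:{lineno}: expected {5 + n_acc} fields, got {len(parts)}")
            marker_ids.append(parts[0])
            chroms.append(parts[1])
            try:
                poss.append(int(parts[2]))
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer position {parts[2]!r}") from None
            aas.append(parts[3])
            abs_.append(parts[4])
            row = np.empty(n_acc, dtype=np.int8)
            for j, cell in enumerate(parts[5:]):
                if cell == "NA":
                    row[j] = MISSING
                elif cell in ("0", "2"):
                    row[j] = np.int8(int(cell))
                else:
                    raise DataError(f"{path}:{lineno}: invalid call {cell!r} (want 0, 2 or NA)")
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no markers")
    return GenotypeMatrix(
        marker_ids=np.array(marker_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        allele_a=np.array(aas, dtype=object),
        allele_b=np.array(abs_, dtype=object),
        calls=np.vstack(rows),
        accession_ids=np.array(accessions, dtype=object),
    )


def _parse_genotype_vcf(path, het_policy: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    marker_ids, chroms, poss, aas, abs_, rows, het_marker = [], [], [], [], [], [], []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise DataError(
                f"{path}: multiallelic site at {var.CHROM}:{var.POS} (ALT={var.ALT}); biallelic SNPs only"
            )
        gts = var.genotype.array()  # (n_samples, ploidy+1); last col phasing
        alleles = gts[:, :-1]
        row = np.empty(len(accessions), dtype=np.int8)
        has_het = False
        for j in range(len(accessions)):
            a = alleles[j]
            if np.any(a < 0):
                row[j] = MISSING
            elif np.all(a == 0):
                row[j] = 0
            elif np.all(a == 1):
                row[j] = 2
            else:  # heterozygous
                has_het = True
                row[j] = MISSING
        mid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        marker_ids.append(mid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        aas.append(var.REF)
        abs_.append(var.ALT[0])
        rows.append(row)
        het_marker.append(has_het)
    if not rows:
        raise DataError(f"{path}: no variants")
    if het_policy == "drop":
        keep = [i for i, h in enumerate(het_marker) if not h]
        if not keep:
            raise DataError(f"{path}: all markers dropped by het_policy='drop'")
        marker_ids = [marker_ids[i] for i in keep]
        chroms = [chroms[i] for i in keep]
        poss = [poss[i] for i in keep]
        aas = [aas[i] for i in keep]
        abs_ = [abs_[i] for i in keep]
        rows = [rows[i] for i in keep]
    return GenotypeMatrix(
        marker_ids=np.array(marker_ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        allele_a=np.array(aas, dtype=object),
        allele_b=np.array(abs_, dtype=object),
        calls=np.vstack(rows),
        accession_ids=np.array(accessions, dtype=object),
    )


def read_genotypes(path, format: str = "tsv", het_policy: str = "missing") -> GenotypeMatrix:
    """Read genotypes from the TSV dialect or a VCF.

    het_policy applies to VCF input only: ``"missing"`` (default) masks each
    heterozygous call as MISSING, preserving the marker; ``"drop"`` removes
    markers containing any heterozygous call.
    """
    if het_policy not in ("missing", "drop"):
        raise ValueError(f"het_policy must be 'missing' or 'drop', got {het_policy!r}")
    if format == "tsv":
        return _parse_genotype_tsv(path)
    if format == "vcf":
        return _parse_genotype_vcf(path, het_policy)
    raise ValueError(f"unknown genotype format: {format!r}")


def read_phenotypes(path) -> PhenotypeTable:
    """Read the phenotype TSV (header: accession_id <trait...>; NA missing)."""
    frame = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={0: str})
    if frame.columns[0] != "accession_id":
        raise DataError(f"{path}: first column must be 'accession_id'")
    frame = frame.set_index("accession_id")
    return PhenotypeTable(frame)


def read_intervals(path) -> pd.DataFrame:
    """Read a BED-like candidate-interval list: chrom, start, end, gene_id.

    ``start`` is 0-based half-open per BED; returned unchanged.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id"],
        dtype={"chrom": str, "gene_id": str},
        comment="#",
    )
    if (df["end"] < df["start"]).any():
        raise DataError(f"{path}: interval with end < start")
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# alignment and grouping


def align_complete_cases(G: GenotypeMatrix, P: PhenotypeTable, trait: str) -> np.ndarray:
    """Accessions present in both inputs with a non-missing value for trait.

    Order follows the genotype matrix, so the result is invariant to row
    order of the phenotype file.
    """
    y = P.trait(trait)
    has_value = set(y.index[y.notna()])
    kept = np.array([a for a in G.accession_ids if a in has_value], dtype=object)
    if kept.size == 0:
        raise DataError(
            f"no accession with genotype data has a value for trait {trait!r}"
        )
    return kept


def genotype_groups(G: GenotypeMatrix, marker: str, accessions=None) -> GenotypeGroups:
    """Group the (sub)sample by genotype call at one marker."""
    i = G.marker_row(marker)
    if accessions is None:
        calls = G.calls[i]
    else:
        calls = G.calls[i, G.accession_indexer(accessions)]
    return groups_from_calls(calls)


def groups_from_calls(calls: np.ndarray) -> GenotypeGroups:
    calls = np.asarray(calls, dtype=np.int8)
    return GenotypeGroups(
        group_index=calls,
        n_low=int(np.count_nonzero(calls == 0)),
        n_high=int(np.count_nonzero(calls == 2)),
    )


def maf(groups: GenotypeGroups) -> float:
    """Minor-allele frequency; equals minor genotype frequency in inbreds.

    Returns 0.0 for a monomorphic marker (K = 1).
    """
    if groups.N == 0:
        raise DataError("cannot compute MAF with no non-missing calls")
    return min(groups.n_low, groups.n_high) / groups.N
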