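"""Phased haplotype cohort I/O.

The universal in-memory representation is :class:`HaplotypeMatrix`: one row
per *haplotype* (a diploid sample contributes two adjacent rows) and one
column per biallelic SNP, coded ``0`` for the reference allele and ``1`` for
the alternate allele.  All generation, auditing and scoring operates on this
matrix; VCF is the exchange format for real cohorts and a plain-text 0/1
table is offered as a light-weight fixture format.

Only phased, biallelic SNP records are representable.  Multiallelic records
and indels are skipped on read (with a logged count); missing or unphased
genotypes are either rejected or cause the whole site to be dropped,
depending on policy — silent imputation is never performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantSite",
    "HaplotypeMatrix",
    "HaplotypeIOError",
    "PhasingError",
    "MissingGenotypeError",
    "TableFormatError",
    "EmptyInputError",
    "read_phased_vcf",
    "read_haplotype_table",
    "write_phased_vcf",
    "write_haplotype_table",
    "filter_by_maf",
    "hamming_distances",
]

_BASES = frozenset("ACGT")


class HaplotypeIOError(ValueError):
    """Base class for cohort I/O failures."""


class PhasingError(HaplotypeIOError):
    """An unphased genotype was encountered under the ``reject`` policy."""


class MissingGenotypeError(HaplotypeIOError):
    """A missing genotype was encountered under the ``reject`` policy."""


class TableFormatError(HaplotypeIOError):
    """The plain haplotype table is malformed (ragged or non-binary)."""


class EmptyInputError(HaplotypeIOError):
    """No usable sites remain after filtering."""


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP: chromosome, 1-based position, id, and the two alleles."""

    chrom: str
    pos: int
    id: str = "."
    ref: str = "A"
    alt: str = "G"

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise HaplotypeIOError(
                f"site {self.chrom}:{self.pos} is not a biallelic SNP "
                f"(ref={self.ref!r}, alt={self.alt!r})"
            )


@dataclass(eq=False)
class HaplotypeMatrix:
    """Binary haplotype rows over an ordered list of biallelic sites.

    Parameters
    ----------
    sites
        Ordered site metadata; positions must be strictly increasing within
        each chromosome.
    rows
        ``(n_haplotypes, n_sites)`` array of 0/1 allele codes.
    row_labels
        One label per haplotype row, conventionally ``"<sample>_<phase>"``.
    meta
        Free-form provenance (e.g. counts of records skipped on read).
    """

    sites: list[VariantSite]
    rows: np.ndarray
    row_labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows)
        if rows.ndim != 2:
            raise HaplotypeIOError("rows must be a 2-D array")
        if rows.size and not np.isin(rows, (0, 1)).all():
            raise HaplotypeIOError("haplotype entries must be 0 or 1")
        self.rows = rows.astype(np.uint8)
        if rows.shape[1] != len(self.sites):
            raise HaplotypeIOError(
                f"row length {rows.shape[1]} != number of sites {len(self.sites)}"
            )
        if len(self.row_labels) != rows.shape[0]:
            raise HaplotypeIOError("one label per haplotype row is required")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise HaplotypeIOError(
                    f"positions not strictly increasing on {s.chrom} at {s.pos}"
                )
            last[s.chrom] = s.pos

    @property
    def n_haplotypes(self) -> int:
        return self.rows.shape[0]

    @property
    def n_sites(self) -> int:
        return self.rows.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele fraction per site."""
        return self.rows.mean(axis=0)

    def subset_rows(self, indices) -> "HaplotypeMatrix":
        indices = np.asarray(indices, dtype=np.intp)
        return HaplotypeMatrix(
            sites=list(self.sites),
            rows=self.rows[indices].copy(),
            row_labels=[self.row_labels[i] for i in indices],
        )

    def subset_sites(self, indices) -> "HaplotypeMatrix":
        indices = np.asarray(indices, dtype=np.intp)
        return HaplotypeMatrix(
            sites=[self.sites[i] for i in indices],
            rows=self.rows[:, indices].copy(),
            row_labels=list(self.row_labels),
        )

    def equals(self, other: "HaplotypeMatrix") -> bool:
        """Exact equality of the 0/1 matrix and site coordinates (labels ignored)."""
        return (
            self.rows.shape == other.rows.shape
            and bool(np.array_equal(self.rows, other.rows))
            and [(s.chrom, s.pos) for s in self.sites]
            == [(s.chrom, s.pos) for s in other.sites]
        )


def _is_biallelic_snp(ref: str, alts: list[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref.upper() in _BASES
        and alts[0].upper() in _BASES
    )


def read_phased_vcf(path, on_missing: str = "reject") -> HaplotypeMatrix:
    """Read a phased diploid (or haploid) VCF into a haplotype matrix.

    Every sample contributes two adjacent rows (one for a haploid sample).
    Sites that are not biallelic SNPs are skipped and counted in
    ``meta["skipped_non_snp"]``.

    Parameters
    ----------
    on_missing
        ``"reject"`` raises on the first missing or unphased genotype;
        ``"drop_site"`` removes any site containing one and counts it in
        ``meta["dropped_sites"]``.
    """
    from cyvcf2 import VCF

    if on_missing not in ("reject", "drop_site"):
        raise ValueError(f"unknown missing-genotype policy {on_missing!r}")

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    sites: list[VariantSite] = []
    skipped_non_snp = 0
    dropped_sites = 0
    ploidy: int | None = None
    for v in vcf:
        if not _is_biallelic_snp(v.REF, v.ALT):
            skipped_non_snp += 1
            continue
        col: list[int] = []
        bad = None  # (reason, sample)
        for sample, gt in zip(samples, v.genotypes):
            alleles, phased = gt[:-1], bool(gt[-1])
            if ploidy is None:
                ploidy = len(alleles)
            if any(a < 0 for a in alleles):
                bad = ("missing", sample)
                break
            if len(alleles) > 1 and not phased:
                bad = ("unphased", sample)
                break
            col.extend(int(a) for a in alleles)
        if bad is not None:
            reason, sample = bad
            if on_missing == "reject":
                exc = MissingGenotypeError if reason == "missing" else PhasingError
                raise exc(
                    f"{reason} genotype at {v.CHROM}:{v.POS} in sample {sample}"
                )
            dropped_sites += 1
            continue
        sites.append(
            VariantSite(chrom=str(v.CHROM), pos=int(v.POS), id=v.ID or ".",
                        ref=v.REF, alt=v.ALT[0])
        )
        columns.append(np.array(col, dtype=np.uint8))
    vcf.close()
    if not sites:
        raise EmptyInputError(f"no usable biallelic SNP sites in {path}")
    rows = np.column_stack(columns)
    if ploidy == 1:
        labels = [f"{s}_0" for s in samples]
    else:
        labels = [f"{s}_{k}" for s in samples for k in range(ploidy or 2)]
    return HaplotypeMatrix(
        sites=sites,
        rows=rows,
        row_labels=labels,
        meta={"skipped_non_snp": skipped_non_snp, "dropped_sites": dropped_sites},
    )


def read_haplotype_table(path) -> HaplotypeMatrix:
    """Read a whitespace-separated 0/1 table, optionally headed by positions.

    A first line whose tokens are integers other than 0/1 is interpreted as
    the base-pair position of each column; otherwise positions default to
    1000, 2000, ... on chromosome "1".
    """
    with open(path) as fh:
        lines = [ln.split() for ln in fh
                 if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise EmptyInputError(f"empty haplotype table {path}")
    positions: list[int] | None = None
    if any(tok not in ("0", "1") for tok in lines[0]):
        try:
            positions = [int(tok) for tok in lines[0]]
        except ValueError as e:
            raise TableFormatError(f"bad header in {path}: {e}") from e
        lines = lines[1:]
        if not lines:
            raise EmptyInputError(f"no data rows in {path}")
    width = len(lines[0])
    rows = np.empty((len(lines), width), dtype=np.uint8)
    for i, toks in enumerate(lines):
        if len(toks) != width:
            raise TableFormatError(
                f"ragged row {i + 1}: {len(toks)} tokens, expected {width}"
            )
        for j, tok in enumerate(toks):
            if tok == "0":
                rows[i, j] = 0
            elif tok == "1":
                rows[i, j] = 1
            else:
                raise TableFormatError(f"non-binary token {tok!r} in row {i + 1}")
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(width)]
    elif len(positions) != width:
        raise TableFormatError(
            f"header lists {len(positions)} positions for {width} columns"
        )
    sites = [VariantSite(chrom="1", pos=p) for p in positions]
    return HaplotypeMatrix(
        sites=sites,
        rows=rows,
        row_labels=[f"hap{i}_0" for i in range(rows.shape[0])],
    )


def write_haplotype_table(matrix: HaplotypeMatrix, path, header: bool = True) -> None:
    """Write the plain 0/1 table (inverse of :func:`read_haplotype_table`)."""
    with open(path, "w") as fh:
        if header:
            fh.write(" ".join(str(p) for p in matrix.positions) + "\n")
        for row in matrix.rows:
            fh.write(" ".join(str(int(a)) for a in row) + "\n")


def write_phased_vcf(matrix: HaplotypeMatrix, path, pairing: str = "consecutive") -> None:
    """Write the matrix as a phased VCF 4.2 file.

    ``pairing="consecutive"`` emits rows ``2k`` and ``2k+1`` as diploid sample
    ``S<k>`` with genotype ``a|b`` (row count must be even);
    ``pairing="none"`` emits every haplotype as its own haploid sample.
    The written file round-trips bit-identically through
    :func:`read_phased_vcf` on the 0/1 matrix.
    """
    if pairing not in ("consecutive", "none"):
        raise ValueError(f"unknown pairing policy {pairing!r}")
    n = matrix.n_haplotypes
    if pairing == "consecutive" and n % 2:
        raise HaplotypeIOError(
            f"consecutive pairing needs an even row count, got {n}"
        )
    if pairing == "consecutive":
        sample_names = [f"S{k}" for k in range(n // 2)]
    else:
        sample_names = [f"S{k}" for k in range(n)]
    seen: list[str] = []
    for s in matrix.sites:
        if s.chrom not in seen:
            seen.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=logicgen\n")
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for j, site in enumerate(matrix.sites):
            col = matrix.rows[:, j]
            if pairing == "consecutive":
                gts = [f"{col[2 * k]}|{col[2 * k + 1]}" for k in range(n // 2)]
            else:
                gts = [str(int(a)) for a in col]
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.id}\t{site.ref}\t{site.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def filter_by_maf(matrix: HaplotypeMatrix, min_maf: float) -> HaplotypeMatrix:
    """Retain sites whose minor allele frequency is ``>= min_maf``.

    MAF is ``min(f, 1 - f)`` with ``f`` the alternate-allele fraction over
    haplotype rows.  The comparison is done on allele *counts* so that the
    boundary case (e.g. 1 carrier in 100 rows at ``min_maf=0.01``) is kept
    exactly, free of float round-off.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    if matrix.n_haplotypes == 0:
        raise EmptyInputError("empty matrix")
    n = matrix.n_haplotypes
    alt = matrix.rows.sum(axis=0, dtype=np.int64)
    minor = np.minimum(alt, n - alt)
    keep = np.flatnonzero(minor >= min_maf * n - 1e-9)
    return matrix.subset_sites(keep)


def hamming_distances(matrix: HaplotypeMatrix, query) -> np.ndarray:
    """Hamming distance from every row to ``query`` (row index or 0/1 vector)."""
    if np.isscalar(query) or (isinstance(query, np.ndarray) and query.ndim == 0):
        q = matrix.rows[int(query)]
    else:
        q = np.asarray(query, dtype=np.uint8)
        if q.shape != (matrix.n_sites,):
            raise ValueError(
                f"query length {q.shape} does not match site count {matrix.n_sites}"
            )
    return np.count_nonzero(matrix.rows != q[None, :], axis=1)
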