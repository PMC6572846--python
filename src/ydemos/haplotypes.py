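"""Haploid biallelic SNP matrices and their VCF 4.2 representation.

The in-memory container is a samples x sites 0/1 matrix (0 = ancestral,
1 = derived), the natural shape for male Y-chromosome data where every
genotype is haploid and every site biallelic.  VCF I/O goes through pysam;
genotypes are written as single haploid alleles (``0`` or ``1``) with no
phase separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam


@dataclass
class HaplotypeMatrix:
    """Haploid 0/1 genotypes for ``n_samples`` samples at ``n_sites`` sites.

    Attributes
    ----------
    genotypes
        ``(n_samples, n_sites)`` array of 0/1 values (uint8).
    samples
        Sample identifiers, one per row.
    positions
        1-based site positions, one per column, strictly increasing.
    contig
        Contig name used on VCF export.
    """

    genotypes: np.ndarray
    samples: list[str]
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    contig: str = "Y"

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x sites array")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("genotypes must be 0/1")
        if len(self.samples) != self.genotypes.shape[0]:
            raise ValueError("sample count does not match genotype rows")
        if self.positions is None:
            self.positions = np.arange(1, self.genotypes.shape[1] + 1)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape != (self.genotypes.shape[1],):
            raise ValueError("positions must match genotype columns")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.contig == other.contig
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.genotypes, other.genotypes)
        )


def write_vcf(matrix: HaplotypeMatrix, path) -> None:
    """Write a haploid biallelic VCF 4.2 file (uncompressed text)."""
    header = pysam.VariantHeader()
    length = int(matrix.positions.max()) if matrix.n_sites else 1
    header.contigs.add(matrix.contig, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for name in matrix.samples:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(matrix.n_sites):
            rec = out.new_record(
                contig=matrix.contig,
                start=int(matrix.positions[j]) - 1,
                stop=int(matrix.positions[j]),
                alleles=("A", "G"),
            )
            for i, name in enumerate(matrix.samples):
                rec.samples[name]["GT"] = (int(matrix.genotypes[i, j]),)
            out.write(rec)


def read_vcf(path) -> HaplotypeMatrix:
    """Read a haploid biallelic VCF into a :class:`HaplotypeMatrix`.

    Raises
    ------
    ValueError
        If a record is multi-allelic or any genotype is not haploid,
        naming the offending record.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: list[np.ndarray] = []
        positions: list[int] = []
        contig = "Y"
        for rec in vcf:
            where = f"{rec.chrom}:{rec.pos}"
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"multi-allelic record at {where}")
            col = np.empty(len(samples), dtype=np.uint8)
            for i, name in enumerate(samples):
                gt = rec.samples[name]["GT"]
                if len(gt) != 1 or gt[0] is None:
                    raise ValueError(
                        f"non-haploid genotype {gt} for sample {name} at {where}"
                    )
                if gt[0] not in (0, 1):
                    raise ValueError(f"non-biallelic allele at {where}")
                col[i] = gt[0]
            columns.append(col)
            positions.append(rec.pos)
            contig = rec.chrom
    if not columns:
        raise ValueError("VCF contains no records")
    genotypes = np.stack(columns, axis=1)
    return HaplotypeMatrix(genotypes, samples, np.array(positions), contig)
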