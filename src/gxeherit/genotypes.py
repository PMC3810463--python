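"""Genotype container and PLINK bed/bim/fam input/output.

Dosages are counts of the A1 allele in {0, 1, 2}; missing calls are NaN so
that no valid dosage value doubles as a sentinel.  The binary .bed dialect is
SNP-major: magic bytes 0x6C 0x1B, mode byte 0x01, then per SNP ceil(n/4)
bytes of 2-bit genotype codes packed least-significant-bits-first
(00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "PlinkFormatError", "read_plink", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# 2-bit code -> A1 dosage
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a .bed file does not match the supported dialect."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP metadata.

    Attributes
    ----------
    fid, iid : arrays of str, length n
    snp_ids : array of str, length m
    chrom : array of str, length m
    pos : int array, 1-based base-pair positions
    a1, a2 : allele codes per SNP (a1 is the counted allele)
    dosage : (n, m) float array in {0, 1, 2, NaN}
    """

    fid: np.ndarray
    iid: np.ndarray
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.fid = np.asarray(self.fid, dtype=object)
        self.iid = np.asarray(self.iid, dtype=object)
        for name in ("snp_ids", "chrom", "a1", "a2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.fid) != n or len(self.iid) != n:
            raise ValueError("sample id length does not match dosage rows")
        if not all(len(getattr(self, a)) == m for a in ("snp_ids", "chrom", "pos", "a1", "a2")):
            raise ValueError("SNP metadata length does not match dosage columns")
        if np.any(self.pos < 1):
            raise ValueError("bim positions are 1-based; found pos < 1")
        if np.any(self.a1 == self.a2):
            raise ValueError("a1 and a2 must differ for every SNP")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids; raises on unknown ids."""
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        out = []
        for s in snp_ids:
            if s not in lookup:
                raise KeyError(f"unknown SNP id: {s}")
            out.append(lookup[s])
        return np.asarray(out, dtype=int)

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        j = self.snp_index(snp_ids)
        return GenotypeMatrix(
            self.fid, self.iid, self.snp_ids[j], self.chrom[j], self.pos[j],
            self.a1[j], self.a2[j], self.dosage[:, j],
        )

    def subset_samples(self, rows: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.fid[rows], self.iid[rows], self.snp_ids, self.chrom, self.pos,
            self.a1, self.a2, self.dosage[rows],
        )


def _pack_bed_column(dosage_col: np.ndarray) -> np.ndarray:
    codes = np.full(dosage_col.shape, 0b01, dtype=np.uint8)  # missing
    codes[dosage_col == 2] = 0b00
    codes[dosage_col == 1] = 0b10
    codes[dosage_col == 0] = 0b11
    n = len(codes)
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    return (quads[:, 0] | quads[:, 1] << 2 | quads[:, 2] << 4 | quads[:, 3] << 6).astype(np.uint8)


def write_plink(genotypes: GenotypeMatrix, prefix, fam: pd.DataFrame | None = None) -> None:
    """Write bed/bim/fam files under ``prefix``.

    ``fam`` may supply pedigree columns (fid iid father mother sex); phenotype
    is written as -9.  Without it, parents are 0 and sex unknown.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = genotypes.n_samples

    if fam is not None:
        fam = fam.set_index("iid").loc[genotypes.iid].reset_index()
        father, mother, sex = fam["father"], fam["mother"], fam["sex"]
    else:
        father = mother = ["0"] * n
        sex = [0] * n
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i in range(n):
            fh.write(
                f"{genotypes.fid[i]} {genotypes.iid[i]} {father[i]} {mother[i]} {sex[i]} -9\n"
            )

    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(genotypes.n_snps):
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.snp_ids[j]}\t0\t{genotypes.pos[j]}"
                f"\t{genotypes.a1[j]}\t{genotypes.a2[j]}\n"
            )

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        for j in range(genotypes.n_snps):
            fh.write(_pack_bed_column(genotypes.dosage[:, j]).tobytes())


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read bed/bim/fam files; returns the genotypes and the fam table.

    Only the SNP-major bed dialect is supported; individual-major files and
    files with bad magic bytes raise :class:`PlinkFormatError`.
    """
    prefix = Path(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not prefix.with_suffix(ext).exists():
            raise FileNotFoundError(prefix.with_suffix(ext))

    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"], dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _MAGIC:
        raise PlinkFormatError("bad .bed magic bytes")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError("individual-major .bed files are not supported")
    bpc = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bpc * m:
        raise PlinkFormatError(
            f"bed payload is {len(body)} bytes; expected {bpc * m} for {n} x {m}"
        )
    body = body.reshape(m, bpc)
    codes = np.empty((m, bpc * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)

    gm = GenotypeMatrix(
        fam["fid"].to_numpy(), fam["iid"].to_numpy(), bim["snp_id"].to_numpy(),
        bim["chrom"].to_numpy(), bim["pos"].to_numpy(), bim["a1"].to_numpy(),
        bim["a2"].to_numpy(), dosage,
    )
    return gm, fam
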