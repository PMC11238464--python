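"""Reading and writing PLINK 1 binary genotype filesets (.bed/.bim/.fam).

Only the SNP-major v1.00 .bed dialect is supported (magic bytes
``0x6c 0x1b`` followed by mode byte ``0x01``), which is what every modern
tool writes.  Dosages count copies of the A1 allele: the 2-bit codes are

====  ==========================  ======
code  genotype                    dosage
====  ==========================  ======
0b00  homozygous A1/A1            2
0b01  missing                     NaN
0b10  heterozygous A1/A2          1
0b11  homozygous A2/A2            0
====  ==========================  ======

Codes are packed little-endian, four samples per byte.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

BIM_COLUMNS = ["chrom", "snp_id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

# code -> A1 dosage lookup for the four 2-bit states
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam fileset is malformed or unsupported."""


def read_bim(path: str | os.PathLike) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", names=BIM_COLUMNS, dtype={"chrom": str})
    if bim["snp_id"].duplicated().any():
        dups = bim.loc[bim["snp_id"].duplicated(), "snp_id"].tolist()
        raise PlinkFormatError(f"{path}: duplicate SNP ids {dups[:5]}")
    return bim


def read_fam(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", names=FAM_COLUMNS, dtype={"fid": str, "iid": str})


def read_bed(path: str | os.PathLike, n_samples: int, n_snps: int) -> np.ndarray:
    """Decode a SNP-major .bed into an (n_samples, n_snps) float dosage matrix."""
    raw = np.fromfile(path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _MAGIC:
        raise PlinkFormatError(f"{path}: bad magic bytes; not a PLINK .bed file")
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{path}: individual-major .bed (mode byte 0x{raw[2]:02x}) is not supported"
        )
    bytes_per_snp = (n_samples + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"{path}: expected {bytes_per_snp * n_snps} data bytes for "
            f"{n_samples} samples x {n_snps} SNPs, found {len(body)}"
        )
    blocks = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    return _CODE_TO_DOSAGE[codes].T.copy()


def write_bed(path: str | os.PathLike, dosages: np.ndarray) -> None:
    """Encode an (n_samples, n_snps) dosage matrix as SNP-major .bed."""
    n_samples, n_snps = dosages.shape
    codes = np.full(dosages.T.shape, 0b01, dtype=np.uint8)  # missing by default
    d = dosages.T
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    bytes_per_snp = (n_samples + 3) // 4
    padded = np.full((n_snps, bytes_per_snp * 4), 0b00, dtype=np.uint8)
    padded[:, :n_samples] = codes
    grouped = padded.reshape(n_snps, bytes_per_snp, 4)
    packed = (
        grouped[:, :, 0]
        | (grouped[:, :, 1] << 2)
        | (grouped[:, :, 2] << 4)
        | (grouped[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(_MAGIC + bytes([_SNP_MAJOR]))
        packed.tofile(fh)


def write_plink(prefix: str | os.PathLike, sample_ids, snp_map: pd.DataFrame, dosages: np.ndarray) -> None:
    """Write a full .bed/.bim/.fam fileset.

    ``snp_map`` must carry columns chrom, snp_id, pos, a1, a2 (cM written as 0).
    """
    prefix = os.fspath(prefix)
    bim = pd.DataFrame(
        {
            "chrom": snp_map["chrom"].astype(str),
            "snp_id": snp_map["snp_id"],
            "cm": 0,
            "pos": snp_map["pos"].astype(int),
            "a1": snp_map["a1"],
            "a2": snp_map["a2"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    write_bed(prefix + ".bed", dosages)
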