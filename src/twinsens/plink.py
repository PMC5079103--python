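"""Minimal PLINK 1 .bed/.bim/.fam codec.

Variant-major (SNP-major) .bed layout: 3 magic bytes ``6C 1B 01`` followed
by ceil(n_samples/4) bytes per variant, 2 bits per sample, least
significant pair first:

====  =====================================
bits  genotype
====  =====================================
00    homozygous A1  (dosage 2, A1 = effect allele here)
01    missing
10    heterozygous   (dosage 1)
11    homozygous A2  (dosage 0)
====  =====================================
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset

MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code per dosage of the A1 allele
_CODE_FOR_DOSAGE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(IOError):
    """A .bed/.bim/.fam triple is malformed or inconsistent."""


def write_plink(dataset: GenotypeDataset, prefix: str | os.PathLike) -> list[str]:
    """Write ``dataset`` as ``prefix``.bed/.bim/.fam. Returns paths written."""
    prefix = os.fspath(prefix)
    bim = dataset.variants
    fam_path, bim_path, bed_path = (
        prefix + ".fam", prefix + ".bim", prefix + ".bed")

    with open(fam_path, "w") as fh:
        for sid in dataset.samples:
            # family id = sample id; parents, sex, phenotype unknown
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")

    with open(bim_path, "w") as fh:
        for _, v in bim.iterrows():
            fh.write(
                f"{v['chromosome']}\t{v['variant_id']}\t0\t"
                f"{int(v['position'])}\t{v['effect_allele']}\t"
                f"{v['other_allele']}\n"
            )

    n = dataset.n_samples
    n_bytes = (n + 3) // 4
    with open(bed_path, "wb") as fh:
        fh.write(MAGIC)
        for j in range(dataset.n_variants):
            col = dataset.dosage[:, j]
            codes = np.full(n, 0b01, dtype=np.uint8)  # missing
            for dose, code in _CODE_FOR_DOSAGE.items():
                codes[col == dose] = code
            packed = np.zeros(n_bytes, dtype=np.uint8)
            for k in range(4):
                part = codes[k::4]
                packed[: len(part)] |= part << (2 * k)
            fh.write(packed.tobytes())
    return [bed_path, bim_path, fam_path]


def read_plink(prefix: str | os.PathLike) -> GenotypeDataset:
    """Read a .bed/.bim/.fam triple into a :class:`GenotypeDataset`.

    Dosages count copies of the A1 allele (stored as effect allele).
    """
    prefix = os.fspath(prefix)
    fam_path, bim_path, bed_path = (
        prefix + ".fam", prefix + ".bim", prefix + ".bed")
    for p in (fam_path, bim_path, bed_path):
        if not os.path.exists(p):
            raise PlinkFormatError(f"missing file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    samples = list(fam["iid"])

    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["chromosome", "variant_id", "cm", "position",
                             "effect_allele", "other_allele"],
                      dtype={"chromosome": str, "variant_id": str,
                             "effect_allele": str, "other_allele": str})

    n, m = len(samples), len(bim)
    n_bytes = (n + 3) // 4
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic != MAGIC:
            raise PlinkFormatError(
                f"{bed_path}: bad magic bytes {magic.hex()} "
                "(expected variant-major PLINK bed)")
        payload = fh.read()
    if len(payload) != n_bytes * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {n_bytes * m} data bytes for "
            f"{n} samples x {m} variants, found {len(payload)}")

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(m, n_bytes)
    dosage = np.empty((n, m), dtype=float)
    for k in range(4):
        codes_k = (raw >> (2 * k)) & 0b11  # (m, n_bytes)
        cols = codes_k[:, : (n - k + 3) // 4]
        dosage[k::4, :] = _DOSAGE_FOR_CODE[cols].T

    variants = bim[["variant_id", "chromosome", "position",
                    "effect_allele", "other_allele"]].copy()
    ds = GenotypeDataset(variants=variants.assign(allele_frequency=np.nan),
                         samples=samples, dosage=dosage)
    ds.variants["allele_frequency"] = ds.effect_allele_frequency()
    return ds
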