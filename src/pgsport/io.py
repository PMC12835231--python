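"""Genotype and table I/O.

Readers for PLINK .bed/.bim/.fam (minimal 2-bit codec, SNP-major), PLINK
.raw-style dosage TSV, and VCF (via cyvcf2, biallelic GT records only);
writers for the matching formats and for the pipeline's TSV/JSON outputs.
Internal variant indices are 0-based; positions in files are 1-based.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_raw",
    "write_raw",
    "read_bim",
    "write_bim",
    "read_plink",
    "write_plink",
    "read_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_table",
    "write_json",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1 .bed
# 2-bit codes -> dosage of the A1 allele (01 = missing)
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


def write_raw(path, G: GenotypeMatrix) -> None:
    """Dosage TSV: sample_id, deme, then one effect-allele count column per
    variant named ``<id>_<alt>``."""
    cols = [f"{v}_{a}" for v, a in zip(G.variant_meta["id"], G.variant_meta["alt"])]
    df = pd.DataFrame(G.dosages, columns=cols)
    df.insert(0, "deme", G.deme_label)
    df.insert(0, "sample_id", G.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_raw(path, variant_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    dosage_cols = [c for c in df.columns if c not in ("sample_id", "deme")]
    if variant_meta is None:
        ids, alts = zip(*(c.rsplit("_", 1) for c in dosage_cols))
        variant_meta = pd.DataFrame(
            {"id": ids, "chrom": 1, "pos": np.arange(1, len(ids) + 1),
             "ref": "N", "alt": alts}
        )
    return GenotypeMatrix(
        dosages=df[dosage_cols].to_numpy(dtype=np.int8),
        sample_ids=df["sample_id"].to_numpy(dtype=str),
        variant_meta=variant_meta,
        deme_label=df["deme"].to_numpy(dtype=str)
        if "deme" in df else np.full(len(df), "unknown"),
    )


def write_bim(path, variant_meta: pd.DataFrame) -> None:
    """PLINK .bim: chrom, id, cM (0), pos, A1 (alt), A2 (ref)."""
    pd.DataFrame(
        {
            "chrom": variant_meta["chrom"],
            "id": variant_meta["id"],
            "cm": 0,
            "pos": variant_meta["pos"],
            "a1": variant_meta["alt"],
            "a2": variant_meta["ref"],
        }
    ).to_csv(path, sep="\t", index=False, header=False)


def read_bim(path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"])
    return pd.DataFrame(
        {"id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"],
         "ref": bim["a2"], "alt": bim["a1"]}
    )


def write_plink(prefix, G: GenotypeMatrix) -> None:
    """Minimal PLINK 1 fileset writer (.bed SNP-major, .bim, .fam).
    A1 is the alt/effect allele, so stored codes count alt dosage."""
    prefix = Path(prefix)
    write_bim(prefix.with_suffix(".bim"), G.variant_meta)
    pd.DataFrame(
        {"fid": G.deme_label, "iid": G.sample_ids, "pat": 0, "mat": 0,
         "sex": 0, "pheno": -9}
    ).to_csv(prefix.with_suffix(".fam"), sep="\t", index=False, header=False)
    n, m = G.dosages.shape
    out = bytearray(_BED_MAGIC)
    for j in range(m):
        codes = np.array([_BED_ENCODE[int(d)] for d in G.dosages[:, j]],
                         dtype=np.uint8)
        padded = np.zeros(-(-n // 4) * 4, dtype=np.uint8)
        padded[:n] = codes
        byts = (padded[0::4] | (padded[1::4] << 2) | (padded[2::4] << 4)
                | (padded[3::4] << 6))
        out.extend(byts.tobytes())
    prefix.with_suffix(".bed").write_bytes(bytes(out))


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam fileset; dosages count the A1 allele.
    Missing genotypes are mean-imputed (rounded), with a logged count."""
    prefix = Path(prefix)
    meta = read_bim(prefix.with_suffix(".bim"))
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK .bed file")
    n, m = len(fam), len(meta)
    bpv = -(-n // 4)
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bpv * m:
        raise ValueError("bed payload size does not match .bim/.fam")
    body = body.reshape(m, bpv)
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T.copy()
    n_missing = int((dosages == -1).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotypes", n_missing)
        d = dosages.astype(float)
        d[d == -1] = np.nan
        fill = np.round(np.nanmean(d, axis=0))
        ii, jj = np.where(dosages == -1)
        dosages[ii, jj] = fill[jj].astype(np.int8)
    return GenotypeMatrix(
        dosages=dosages.astype(np.int8),
        sample_ids=fam["iid"].to_numpy(dtype=str),
        variant_meta=meta,
        deme_label=fam["fid"].to_numpy(dtype=str),
    )


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF; dosage is the ALT allele count.
    Multi-allelic records are skipped with a logged count; missing genotypes
    are mean-imputed (rounded) with a logged count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=str)
    rows, meta = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(rec.gt_types)  # 0=homref 1=het 2=missing 3=homalt
        d = np.select([gts == 0, gts == 1, gts == 3], [0, 1, 2], default=-1)
        rows.append(d.astype(np.int8))
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                     rec.REF, rec.ALT[0]))
    if n_multi:
        logger.info("skipped %d multi-allelic records", n_multi)
    dosages = np.array(rows, dtype=np.int8).T
    n_missing = int((dosages == -1).sum())
    if n_missing:
        logger.info("mean-imputing %d missing genotypes", n_missing)
        d = dosages.astype(float)
        d[d == -1] = np.nan
        fill = np.round(np.nanmean(d, axis=0))
        ii, jj = np.where(dosages == -1)
        dosages[ii, jj] = fill[jj].astype(np.int8)
    variant_meta = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(
        dosages=dosages,
        sample_ids=samples,
        variant_meta=variant_meta,
        deme_label=np.full(len(samples), "unknown"),
    )


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Dispatch on format: 'plink' (bed/bim/fam prefix), 'raw', or 'vcf'.
    Inferred from the extension when not given."""
    p = Path(path)
    if format is None:
        format = {".vcf": "vcf", ".raw": "raw", ".tsv": "raw",
                  ".bed": "plink"}.get(p.suffix, None)
        if format is None:
            raise ValueError(f"cannot infer genotype format from {p.name!r}")
    if format == "vcf":
        return read_vcf(p)
    if format == "raw":
        return read_raw(p)
    if format == "plink":
        return read_plink(p.with_suffix("") if p.suffix == ".bed" else p)
    raise ValueError(f"unknown genotype format: {format!r}")


def write_phenotypes(path, pheno: pd.DataFrame) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _header_comment(seed, config_hash) -> str:
    from . import __version__

    return f"# pgsport {__version__} seed={seed} config={config_hash}\n"


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_table(path, df: pd.DataFrame, seed=None, chash="-") -> None:
    """TSV with a provenance header comment (tool version, seed, config)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, chash))
        df.to_csv(fh, sep="\t", index=False)


def write_json(path, obj: dict, seed=None, chash="-") -> None:
    meta = {"_pgsport": {"seed": seed, "config": chash}}
    Path(path).write_text(json.dumps({**meta, **obj}, indent=2, default=float))
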