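"""Genotype containers and file I/O.

Dosages (expected copies of the alternate allele, real-valued in [0, 2]) are
held as a variants x samples matrix with NaN as the missing sentinel.  Two
on-disk formats are supported: VCF 4.x with per-sample dosage in the DS
FORMAT field (GP and hard GT as fallbacks, the usual imputation-output
convention) and a tab-delimited dosage table with variants as rows.
Coordinates are 1-based as in VCF.  Multi-allelic sites are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotypes", "write_vcf", "write_dosage_table"]

_VARIANT_COLS = ["chrom", "pos", "id", "ref", "alt", "typed", "imputation_r2"]


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix plus variant metadata.

    `variants` carries chrom, pos (1-based), id, ref, alt, typed flag and
    imputation_r2; `dosage` is float with NaN for missing calls.
    """

    variants: pd.DataFrame
    dosage: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-d (variants x samples)")
        if len(self.variants) != self.dosage.shape[0]:
            raise ValueError("variants/dosage row mismatch")
        if self.samples and len(self.samples) != self.dosage.shape[1]:
            raise ValueError("samples/dosage column mismatch")
        ids = self.variants["id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[1]

    def index_of(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"unknown variant id {variant_id!r}")
        return int(hits[0])

    def get(self, variant_id: str) -> np.ndarray:
        """Dosage row for one variant id."""
        return self.dosage[self.index_of(variant_id)]

    def subset(self, mask) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return GenotypeMatrix(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[idx],
            samples=list(self.samples),
        )


class GenotypeParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    return "." if np.isnan(x) else f"{x:.4g}"


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write an uncompressed VCF 4.2 with DS per sample and TYPED/R2 INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(gm.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation accuracy r-squared">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        for i, v in gm.variants.iterrows():
            info = []
            if bool(v["typed"]):
                info.append("TYPED")
            info.append(f"R2={float(v['imputation_r2']):.4g}")
            row = [
                str(v["chrom"]),
                str(int(v["pos"])),
                str(v["id"]),
                str(v["ref"]),
                str(v["alt"]),
                ".",
                "PASS",
                ";".join(info),
                "DS",
            ] + [_fmt(x) for x in gm.dosage[i]]
            fh.write("\t".join(row) + "\n")


def write_dosage_table(gm: GenotypeMatrix, path) -> None:
    """Tab-delimited dosage table: variant metadata columns then one column
    per sample id; missing written as NA."""
    df = gm.variants[_VARIANT_COLS].copy()
    dos = pd.DataFrame(gm.dosage, columns=gm.samples)
    pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def _format_field(var, key):
    try:
        return var.format(key)
    except KeyError:
        return None


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    recs, rows = [], []
    ids_seen = set()
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise GenotypeParseError(
                f"{path}: record {k + 1} ({var.CHROM}:{var.POS}) is multi-allelic; "
                "decompose before loading"
            )
        vid = var.ID or f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}"
        if vid in ids_seen:
            raise GenotypeParseError(f"{path}: duplicate variant id {vid!r} at record {k + 1}")
        ids_seen.add(vid)
        dos = np.full(len(samples), np.nan)
        ds = _format_field(var, "DS")
        if ds is not None:
            ds = np.asarray(ds, dtype=float).reshape(len(samples), -1)[:, 0]
            ds = np.where(np.isfinite(ds) & (ds >= 0), ds, np.nan)
            dos = ds
        missing = ~np.isfinite(dos)
        if missing.any():
            gp = _format_field(var, "GP")
            if gp is not None:
                gp = np.asarray(gp, dtype=float).reshape(len(samples), -1)
                exp = gp[:, 1] + 2.0 * gp[:, 2]
                ok = np.isfinite(exp)
                dos[missing & ok] = exp[missing & ok]
                missing = ~np.isfinite(dos)
        if missing.any():
            try:
                gt = np.asarray(var.gt_types, dtype=float)  # 0/1/2 copies, 3 = missing
            except Exception:
                gt = None  # record carries no GT field
            if gt is not None:
                gt[gt == 3] = np.nan
                dos[missing] = gt[missing]
        with np.errstate(invalid="ignore"):
            if np.nanmax(dos, initial=0.0) > 2.0 or np.nanmin(dos, initial=0.0) < 0.0:
                raise GenotypeParseError(f"{path}: dosage outside [0,2] at record {k + 1}")
        info = dict(var.INFO)
        recs.append(
            {
                "chrom": var.CHROM,
                "pos": int(var.POS),
                "id": vid,
                "ref": var.REF,
                "alt": var.ALT[0],
                "typed": bool(info.get("TYPED", False)),
                "imputation_r2": float(info.get("R2", np.nan)),
            }
        )
        rows.append(dos)
    if not recs:
        raise GenotypeParseError(f"{path}: no variant records")
    return GenotypeMatrix(variants=pd.DataFrame(recs), dosage=np.vstack(rows), samples=samples)


def _read_dosage_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    missing_meta = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing_meta:
        raise GenotypeParseError(f"{path}: missing metadata columns {missing_meta}")
    samples = [c for c in df.columns if c not in _VARIANT_COLS]
    dosage = df[samples].to_numpy(dtype=float)
    return GenotypeMatrix(variants=df[_VARIANT_COLS].copy(), dosage=dosage, samples=samples)


def read_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Load a genotype matrix from `vcf` or `dosage_table`.

    VCF dosage priority per sample: DS if present, else expected dosage from
    GP, else hard GT; remaining entries are missing (NaN).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path)
    raise ValueError(f"unknown genotype format {format!r}")
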