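"""Reading and writing of the cohort table formats.

Tab-separated text throughout: a MAF-like somatic variant table, a SEG-like
allele-specific copy-number table (1-based inclusive coordinates), a
mitochondrial candidate count table (mirrored as a two-sample VCF 4.2 with
AD/DP FORMAT fields), a genes x samples expression matrix, and a clinical
table. ``write_cohort`` emits all tables plus a JSON manifest with SHA-256
checksums; ``read_cohort`` round-trips them exactly.

BED gene intervals (0-based half-open) are converted to the package's
1-based inclusive convention on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .simulate import SyntheticCohort

__all__ = [
    "write_cohort",
    "read_cohort",
    "read_maf",
    "read_seg",
    "read_mito_tsv",
    "read_expression",
    "read_clinical",
    "read_bed_genes",
    "write_mito_vcf",
    "read_mito_vcf",
]

MAF_DTYPES = {
    "sample_id": str, "chrom": str, "pos": np.int64, "ref": str, "alt": str,
    "variant_class": str, "region": str, "nonsynonymous": bool,
    "clonal": bool, "vaf": float,
}
SEG_DTYPES = {
    "sample_id": str, "chrom": str, "start": np.int64, "end": np.int64,
    "tcn": np.int64, "lcn": float, "log2_ratio": float,
}
MITO_DTYPES = {
    "sample_id": str, "pos": np.int64, "ref": str, "alt": str,
    "n_mut_tum": np.int64, "rd_tum": np.int64, "n_mut_ctrl": np.int64,
    "rd_ctrl": np.int64, "vaf_tum": float, "vaf_ctrl": float,
}


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def _read_tsv(path, dtypes=None, **kw) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", **kw)
    if dtypes:
        for col, dt in dtypes.items():
            if col in df.columns:
                df[col] = df[col].astype(dt)
    return df


def read_maf(path) -> pd.DataFrame:
    return _read_tsv(path, MAF_DTYPES)


def read_seg(path) -> pd.DataFrame:
    return _read_tsv(path, SEG_DTYPES)


def read_mito_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, MITO_DTYPES)


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_clinical(path) -> pd.DataFrame:
    # keep_default_na keeps absent dates as "" so the round-trip is exact;
    # endpoint derivation coerces "" to NaT itself.
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)


def read_bed_genes(path) -> pd.DataFrame:
    """BED (0-based half-open) -> gene intervals, 1-based inclusive."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=range(4),
    )
    out = df[["gene", "chrom"]].copy()
    out["start"] = df["start"].astype(np.int64) + 1
    out["end"] = df["end"].astype(np.int64)
    if (out["end"] < out["start"]).any():
        raise ValidationError("zero- or negative-length BED interval")
    return out


def write_mito_vcf(mito: pd.DataFrame, path: Path) -> None:
    """Mirror the mito candidate table as a two-sample VCF 4.2.

    TUMOR/CONTROL columns carry AD (ref,alt allele depths) and DP.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrM,length=16569>",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Tumour sample id">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tCONTROL",
    ]
    for r in mito.itertuples(index=False):
        tum = f"{int(r.rd_tum) - int(r.n_mut_tum)},{int(r.n_mut_tum)}:{int(r.rd_tum)}"
        ctl = f"{int(r.rd_ctrl) - int(r.n_mut_ctrl)},{int(r.n_mut_ctrl)}:{int(r.rd_ctrl)}"
        lines.append(
            f"chrM\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\t.\t"
            f"SAMPLE={r.sample_id}\tAD:DP\t{tum}\t{ctl}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_mito_vcf(path) -> pd.DataFrame:
    """Parse the VCF written by :func:`write_mito_vcf` back into counts."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
        tum_ad, tum_dp = f[9].split(":")
        ctl_ad, ctl_dp = f[10].split(":")
        n_t = int(tum_ad.split(",")[1])
        n_c = int(ctl_ad.split(",")[1])
        rows.append(
            {
                "sample_id": info.get("SAMPLE", ""),
                "pos": int(f[1]),
                "ref": f[3],
                "alt": f[4],
                "n_mut_tum": n_t,
                "rd_tum": int(tum_dp),
                "n_mut_ctrl": n_c,
                "rd_ctrl": int(ctl_dp),
                "vaf_tum": round(n_t / int(tum_dp), 6),
                "vaf_ctrl": round(n_c / int(ctl_dp), 6),
            }
        )
    df = pd.DataFrame(rows, columns=list(MITO_DTYPES))
    for col, dt in MITO_DTYPES.items():
        df[col] = df[col].astype(dt)
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_cohort(cohort: SyntheticCohort, directory) -> dict:
    """Write every cohort table to ``directory`` and return the manifest.

    The manifest (also saved as ``manifest.json``) lists each file with its
    SHA-256 checksum and row count; it changes iff any table changes.
    """
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        probe = d / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"directory {d} is not writable: {exc}") from exc

    files = {
        "variants": ("variants.maf.tsv", cohort.variants, False),
        "segments": ("segments.seg.tsv", cohort.segments, False),
        "mito": ("mito_counts.tsv", cohort.mito, False),
        "expression": ("expression.tsv", cohort.expression, True),
        "clinical": ("clinical.tsv", cohort.clinical, False),
        "sv": ("sv.tsv", cohort.sv, False),
        "truth": ("truth_samples.tsv", cohort.truth, False),
        "mito_truth": ("truth_mito.tsv", cohort.mito_truth, False),
    }
    manifest: dict = {"files": {}, "attrs": cohort.attrs,
                      "signature_genes": list(cohort.signature_genes)}
    for key, (name, df, index) in files.items():
        path = d / name
        _write_tsv(df, path, index=index)
        manifest["files"][key] = {
            "path": name,
            "sha256": _sha256(path),
            "n_rows": int(len(df)),
        }
    vcf_path = d / "mito.vcf"
    write_mito_vcf(cohort.mito, vcf_path)
    manifest["files"]["mito_vcf"] = {
        "path": "mito.vcf",
        "sha256": _sha256(vcf_path),
        "n_rows": int(len(cohort.mito)),
    }
    sig_path = d / "signature_genes.txt"
    sig_path.write_text("\n".join(cohort.signature_genes) + ("\n" if cohort.signature_genes else ""))
    manifest["files"]["signature_genes"] = {
        "path": "signature_genes.txt",
        "sha256": _sha256(sig_path),
        "n_rows": len(cohort.signature_genes),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_cohort(directory) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    truth = _read_tsv(d / "truth_samples.tsv", {"sample_id": str, "is_hm": bool})
    cohort = SyntheticCohort(
        variants=read_maf(d / "variants.maf.tsv"),
        segments=read_seg(d / "segments.seg.tsv"),
        mito=read_mito_tsv(d / "mito_counts.tsv"),
        expression=read_expression(d / "expression.tsv"),
        clinical=read_clinical(d / "clinical.tsv"),
        sv=_read_tsv(d / "sv.tsv", {"sample_id": str, "sv_type": str}),
        truth=truth,
        mito_truth=_read_tsv(d / "truth_mito.tsv", {"sample_id": str}),
        signature_genes=manifest.get("signature_genes", []),
        attrs=manifest.get("attrs", {}),
    )
    return cohort
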