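"""Tabular and variant-file input/output.

Sib-pair datasets travel as TSV with one row per individual, two rows
per family: columns ``family_id, member, g_causal, g_tested, y, z``.
Results tables are TSV with ``#`` metadata header lines (seed, config
hash, library versions) for lossless round trips.

The optional real-data mode reads genotypes from a VCF (biallelic
sites, GT field; pairs with a missing genotype are excluded per SNP)
and phenotype/pairing from a FAM-style whitespace-delimited pedigree
table (FID IID PID MID SEX PHENO; members of a family are paired by
shared FID).
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .sibpairs import SibPairData

log = logging.getLogger(__name__)

DATASET_COLUMNS = ["family_id", "member", "g_causal", "g_tested", "y", "z"]


def write_dataset(data: SibPairData, path) -> None:
    """Write a sib-pair dataset as TSV, two rows (members 1 and 2) per family."""
    n = data.n_pairs
    rows = {
        "family_id": np.repeat(np.arange(1, n + 1), 2),
        "member": np.tile([1, 2], n),
        "g_causal": np.asarray(data.g_causal).ravel(),
        "g_tested": np.asarray(data.g_tested).ravel(),
        "y": np.asarray(data.y).ravel(),
        "z": np.asarray(data.z).ravel() if data.z is not None else np.full(2 * n, np.nan),
    }
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_dataset(path) -> SibPairData:
    """Read a sib-pair dataset TSV, validating the two-members-per-family pairing."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DATASET_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for fam, grp in df.groupby("family_id", sort=False):
        if sorted(grp["member"]) != [1, 2]:
            first_line = int(grp.index.min()) + 2  # 1-based, after header
            raise ValueError(
                f"{path}: family {fam} (near line {first_line}) does not have exactly "
                "members 1 and 2"
            )
    df = df.sort_values(["family_id", "member"], kind="stable")
    n = df.shape[0] // 2
    z = None
    if "z" in df.columns and not df["z"].isna().all():
        z = df["z"].to_numpy().reshape(n, 2)
    return SibPairData(
        g_causal=df["g_causal"].to_numpy().reshape(n, 2),
        g_tested=df["g_tested"].to_numpy().reshape(n, 2),
        y=df["y"].to_numpy().reshape(n, 2),
        z=z,
    )


def write_results(table: pd.DataFrame, path, metadata: Optional[dict] = None) -> None:
    """Write a results table as TSV with '#'-prefixed metadata header lines."""
    buf = _io.StringIO()
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}={value}\n")
    table.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_results(path, expect_config_hash: Optional[str] = None) -> tuple[pd.DataFrame, dict]:
    """Read a results TSV; returns (table, metadata).

    Logs a warning if ``expect_config_hash`` differs from the stored one
    (resume-with-changed-config protection).
    """
    meta: dict[str, str] = {}
    lines = Path(path).read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = value
    table = pd.read_csv(_io.StringIO("".join(lines[body_start:])), sep="\t")
    if expect_config_hash is not None and meta.get("config_hash") not in (None, expect_config_hash):
        log.warning(
            "config hash mismatch: stored %s, expected %s",
            meta.get("config_hash"),
            expect_config_hash,
        )
    return table, meta


# --- optional real-data mode ------------------------------------------------


def read_pedigree(path) -> pd.DataFrame:
    """FAM-style pedigree: FID IID PID MID SEX PHENO, whitespace delimited."""
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pid", "mid", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    counts = fam.groupby("fid").size()
    bad = counts[counts != 2]
    if len(bad):
        raise ValueError(f"families without exactly two members: {list(bad.index)[:5]}")
    return fam


def read_vcf_genotypes(vcf_path, sample_order: list[str]) -> pd.DataFrame:
    """Dosages (0/1/2 of the ALT allele, NaN for missing) for biallelic SNPs.

    Returns a DataFrame indexed by variant ID (or chrom:pos) with one
    column per sample in ``sample_order``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - environment dependent
        raise ImportError("VCF support requires the cyvcf2 package") from err

    vcf = VCF(str(vcf_path), gts012=True)
    col_idx = [vcf.samples.index(s) for s in sample_order]
    rows, ids = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue
        # with gts012: 0=hom ref, 1=het, 2=hom alt, 3=missing
        dosage = np.asarray(variant.gt_types, dtype=float)
        dosage[dosage == 3] = np.nan
        rows.append(dosage[col_idx])
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    return pd.DataFrame(rows, index=ids, columns=sample_order)


def load_vcf_sibpairs(vcf_path, fam_path) -> tuple[pd.DataFrame, np.ndarray]:
    """Assemble per-SNP sib-pair genotypes and phenotypes from VCF + pedigree.

    Returns ``(genotypes, y)`` where ``genotypes`` has a row per SNP and
    a column per individual (family-major order, NaN for missing calls)
    and ``y`` is the (n_pairs, 2) phenotype array from the FAM file.
    """
    fam = read_pedigree(fam_path)
    fam = fam.sort_values(["fid", "iid"], kind="stable")
    sample_order = list(fam["iid"])
    geno = read_vcf_genotypes(vcf_path, sample_order)
    y = fam["pheno"].to_numpy(dtype=float).reshape(-1, 2)
    return geno, y


def complete_pairs(snp_dosage: np.ndarray) -> np.ndarray:
    """Boolean mask over pairs keeping only those with both calls present."""
    g = np.asarray(snp_dosage, dtype=float).reshape(-1, 2)
    return ~np.isnan(g).any(axis=1)
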