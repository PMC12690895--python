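"""Domain containers, file readers, sample alignment and scale conversions.

The pipeline operates on five rectangular tables sharing one sample axis:

* methylation M values (samples x probes),
* genotype allele dosages in [0, 2] (samples x SNPs),
* exposome variables, numeric-coded (samples x exposures),
* concomitant variables / covariates (samples x covariates),

plus two coordinate manifests (probes and SNPs, 1-based positions).
Everything downstream assumes complete cases in identical sample order;
:func:`load_dataset` / :func:`align` enforce that once, up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("methylgxe")

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}


class DataError(ValueError):
    """Raised on malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _check_manifest(df: pd.DataFrame, id_col: str) -> pd.DataFrame:
    required = {id_col, "chrom", "pos"}
    if not required.issubset(df.columns):
        raise DataError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    if df[id_col].duplicated().any():
        dup = df[id_col][df[id_col].duplicated()].iloc[0]
        raise DataError(f"duplicate id {dup!r} in manifest")
    if (df["pos"] < 1).any():
        raise DataError("manifest positions must be >= 1 (1-based)")
    out = df[[id_col, "chrom", "pos"]].copy()
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(np.int64)
    return out.sort_values(["chrom", "pos", id_col], kind="mergesort").reset_index(drop=True)


def read_probe_manifest(path) -> pd.DataFrame:
    """Read a BED-like probe manifest (probe_id, chrom, pos) as a sorted frame."""
    df = pd.read_csv(path, sep=None, engine="python")
    return _check_manifest(df, "probe_id")


def read_snp_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    return _check_manifest(df, "snp_id")


def manifest_to_bed(manifest: pd.DataFrame, id_col: str) -> pd.DataFrame:
    """Export a 1-based manifest as 0-based half-open BED records."""
    return pd.DataFrame(
        {
            "chrom": manifest["chrom"],
            "start": manifest["pos"] - 1,
            "end": manifest["pos"],
            "name": manifest[id_col],
        }
    )


# ---------------------------------------------------------------------------
# sample x feature tables
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a samples x features TSV/CSV (first column = sample id)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise DataError(f"duplicate sample ids in {path}")
    if df.columns.duplicated().any():
        raise DataError(f"duplicate feature ids in {path}")
    return df


def read_genotype_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read genotypes from a VCF; returns (dosage matrix, SNP manifest).

    Imputed dosage (FORMAT/DS) is used when present, otherwise hard-call GT
    converted to the 0/1/2 count of alternate alleles.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            if (gts < 0).any():
                raise DataError(f"missing genotype at {vid}")
            dose = gts.sum(axis=1).astype(float)
        ids.append(vid)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(dose)
    geno = pd.DataFrame(np.array(rows).T, index=samples, columns=ids)
    manifest = _check_manifest(
        pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss}), "snp_id"
    )
    return geno, manifest


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """Logit2 transform of methylation proportions: log2(beta / (1 - beta))."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise DataError("beta values must lie strictly in (0, 1)")
    out = np.log2(beta / (1.0 - beta))
    return out.item() if out.ndim == 0 else out


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + 2.0 ** (-m))
    return out.item() if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# aligned dataset
# ---------------------------------------------------------------------------

@dataclass
class AlignedDataset:
    """All sample-indexed tables restricted to one common, ordered sample set."""

    methylation: pd.DataFrame
    genotypes: pd.DataFrame
    exposome: pd.DataFrame
    covariates: pd.DataFrame
    probe_manifest: pd.DataFrame = field(repr=False)
    snp_manifest: pd.DataFrame = field(repr=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.methylation.index)

    @property
    def n_samples(self) -> int:
        return len(self.methylation.index)

    def with_ge(self, genotypes: pd.DataFrame, exposome: pd.DataFrame) -> "AlignedDataset":
        return replace(self, genotypes=genotypes, exposome=exposome)


def _validate_cells(name: str, df: pd.DataFrame) -> None:
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise DataError(
            f"missing value in {name} at sample={df.index[r]!r}, feature={df.columns[c]!r}"
        )


def align(
    methylation: pd.DataFrame,
    genotypes: pd.DataFrame,
    exposome: pd.DataFrame,
    covariates: pd.DataFrame,
    probe_manifest: pd.DataFrame,
    snp_manifest: pd.DataFrame,
    autosomes_only: bool = True,
) -> AlignedDataset:
    """Restrict all tables to the intersection of sample ids, in sorted order.

    Fails fast on an empty intersection, missing values in any retained cell,
    out-of-range dosages, constant exposure columns, or a rank-deficient
    covariate design (after adding an intercept). Idempotent.
    """
    common = sorted(
        set(methylation.index)
        & set(genotypes.index)
        & set(exposome.index)
        & set(covariates.index)
    )
    if not common:
        raise DataError("no samples shared across methylation/genotype/exposome/covariates")
    for name, df in (
        ("methylation", methylation),
        ("genotypes", genotypes),
        ("exposome", exposome),
        ("covariates", covariates),
    ):
        dropped = len(df.index) - len(common)
        if dropped:
            logger.info("align: dropping %d samples from %s", dropped, name)

    # canonical manifest order regardless of input file order
    probe_manifest = probe_manifest.sort_values(
        ["chrom", "pos", "probe_id"], kind="mergesort").reset_index(drop=True)
    snp_manifest = snp_manifest.sort_values(
        ["chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)

    if autosomes_only:
        keep_p = probe_manifest["chrom"].isin(AUTOSOMES)
        keep_s = snp_manifest["chrom"].isin(AUTOSOMES)
        if (~keep_p).any():
            logger.info("align: excluding %d non-autosomal probes", int((~keep_p).sum()))
        if (~keep_s).any():
            logger.info("align: excluding %d non-autosomal SNPs", int((~keep_s).sum()))
        probe_manifest = probe_manifest[keep_p].reset_index(drop=True)
        snp_manifest = snp_manifest[keep_s].reset_index(drop=True)

    meth = methylation.loc[common, methylation.columns.intersection(probe_manifest["probe_id"])]
    geno = genotypes.loc[common, genotypes.columns.intersection(snp_manifest["snp_id"])]
    expo = exposome.loc[common].copy()
    covs = covariates.loc[common].copy()

    for name, df in (("methylation", meth), ("genotypes", geno),
                     ("exposome", expo), ("covariates", covs)):
        _validate_cells(name, df)

    g = geno.to_numpy(dtype=float)
    if g.size and ((g < 0) | (g > 2)).any():
        r, c = next(zip(*np.where((g < 0) | (g > 2))))
        raise DataError(
            f"dosage out of [0, 2] for snp={geno.columns[c]!r}, sample={geno.index[r]!r}"
        )
    nun = expo.nunique(axis=0)
    if (nun <= 1).any():
        raise DataError(f"constant exposure column(s): {list(nun.index[nun <= 1])}")

    x = np.column_stack([np.ones(len(common)), covs.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DataError("covariate design is rank-deficient after adding an intercept")

    probe_manifest = probe_manifest[probe_manifest["probe_id"].isin(meth.columns)].reset_index(drop=True)
    snp_manifest = snp_manifest[snp_manifest["snp_id"].isin(geno.columns)].reset_index(drop=True)
    # canonical feature order: manifest order for coordinates, sorted for the rest
    meth = meth.loc[:, list(probe_manifest["probe_id"])]
    geno = geno.loc[:, list(snp_manifest["snp_id"])]
    expo = expo.loc[:, sorted(expo.columns)]
    covs = covs.loc[:, sorted(covs.columns)]
    return AlignedDataset(meth, geno, expo, covs, probe_manifest, snp_manifest)


def load_dataset(
    methylation_path,
    probe_manifest_path,
    genotype_path,
    snp_manifest_path=None,
    exposome_path=None,
    covariate_path=None,
    autosomes_only: bool = True,
) -> AlignedDataset:
    """Load all inputs from disk and return an :class:`AlignedDataset`.

    ``genotype_path`` may be a TSV/CSV dosage matrix (then ``snp_manifest_path``
    is required) or a VCF (``.vcf``/``.vcf.gz``), from which the SNP manifest
    is derived.
    """
    meth = read_matrix(methylation_path)
    probes = read_probe_manifest(probe_manifest_path)
    gpath = str(genotype_path)
    if gpath.endswith((".vcf", ".vcf.gz")):
        geno, snps = read_genotype_vcf(gpath)
    else:
        if snp_manifest_path is None:
            raise DataError("snp_manifest_path is required for matrix genotype input")
        geno = read_matrix(genotype_path)
        snps = read_snp_manifest(snp_manifest_path)
    expo = read_matrix(exposome_path)
    covs = read_matrix(covariate_path)
    return align(meth, geno, expo, covs, probes, snps, autosomes_only=autosomes_only)
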