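"""Ground-truth-labelled synthetic datasets for end-to-end verification.

The generator emulates the statistical structure the pipeline's models
assume: biallelic allele dosages at chosen MAF, a mixed continuous/binary
exposome, Gaussian concomitant variables with linear effects on M values,
and planted loci whose methylation carries genetic (G), environmental (E),
additive (G+E) or interactive (GxE) signal — or none (B) — on top of a
shared latent regional factor and probe-level noise.

Layout: each planted locus occupies its own block on a chromosome, blocks
spaced far enough apart (default 2.5 Mb) that cis windows do not overlap;
its cis SNPs are placed within +-0.9 Mb of the locus. VMR-kind loci get
2-5 clustered probes (gaps ~ U[50, 800] bp), sVMP-kind loci one isolated
probe. Low-variance filler probes (isolated, > 1 kb from everything) pad the
array so planted probes sit in the top variance decile.

Effect sizes are parameterized as target partial R^2 of each model term in
the summarized (median) locus methylation, so acceptance thresholds carry
across sample sizes. The within-region correlation rho is induced by the
shared component; probe noise is sized so that the expected adjacent-pair
Pearson correlation equals rho, and the median-of-m noise attenuation is
accounted for when solving the effect scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import AlignedDataset, DataError, _check_manifest

INFORMATIVE_CLASSES = ("G", "E", "GE_ADD", "GXE")
ALL_CLASSES = ("B",) + INFORMATIVE_CLASSES

# Var(median of m iid standard normals), m = 1..30 (Monte Carlo, 4e6 reps).
# Used to attenuate probe noise when calibrating effects on the median
# summary of an m-probe region.
_MEDIAN_VAR = np.array([
    1.0009, 0.5004, 0.4487, 0.2980, 0.2871, 0.2146, 0.2103, 0.1684, 0.1660,
    0.1385, 0.1371, 0.1174, 0.1169, 0.1023, 0.1017, 0.0903, 0.0901, 0.0811,
    0.0808, 0.0734, 0.0732, 0.0672, 0.0671, 0.0619, 0.0616, 0.0573, 0.0573,
    0.0534, 0.0534, 0.0500,
])


@dataclass
class SimConfig:
    """Simulation conditions; defaults are the package's reference recovery
    scenario (n=500, 20 loci per class, per-term partial R^2 0.2)."""

    n_samples: int = 500
    loci_per_class: dict[str, int] = field(
        default_factory=lambda: {c: 20 for c in ALL_CLASSES}
    )
    partial_r2: float = 0.2          # target per model term
    vmr_fraction: float = 0.5        # fraction of loci that are multi-probe VMRs
    vmr_probe_range: tuple[int, int] = (2, 5)
    rho: float = 0.7                 # within-region probe correlation
    latent_sd: float = 1.0           # shared regional factor (M-value scale)
    filler_noise_sd: float = 0.6
    covar_beta_sd: float = 0.3
    n_covariates: int = 4
    cis_per_locus: int = 10
    n_exposures: int = 15
    binary_exposure_fraction: float = 0.5
    maf_range: tuple[float, float] = (0.1, 0.5)
    locus_spacing: int = 2_500_000
    hvp_fill_factor: float = 10.0    # total probes = fill_factor * planted probes
    n_chromosomes: int = 22
    seed: int = 0

    def validate(self):
        if any(n < 0 for n in self.loci_per_class.values()):
            raise DataError("loci counts must be non-negative")
        if not 0 < self.partial_r2 < 1:
            raise DataError("partial_r2 must be in (0, 1)")
        if not 0 < self.rho < 1:
            raise DataError("rho must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise DataError("maf_range must lie in (0, 0.5]")


@dataclass
class Locus:
    locus_id: str
    true_class: str
    kind: str  # "VMR" | "sVMP"
    chrom: str
    positions: list[int]
    probe_ids: list[str]
    causal_snp: str | None = None
    causal_exposure: str | None = None
    effect_sizes: dict[str, float] = field(default_factory=dict)


def _n_terms(cls: str) -> dict[str, bool]:
    return {
        "g": cls in ("G", "GE_ADD", "GXE"),
        "e": cls in ("E", "GE_ADD", "GXE"),
        "gxe": cls == "GXE",
    }


def _draw_nonconstant(rng, draw, max_tries=20):
    for _ in range(max_tries):
        v = draw(rng)
        if np.unique(v).size > 1:
            return v
    raise DataError("could not draw a non-constant column")


def simulate(config: SimConfig) -> tuple[AlignedDataset, list[Locus]]:
    """Generate a complete aligned dataset plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    sample_ids = [f"s{i:04d}" for i in range(n)]
    covariates = pd.DataFrame(
        rng.standard_normal((n, config.n_covariates)),
        index=sample_ids,
        columns=[f"cov{i + 1}" for i in range(config.n_covariates)],
    )

    expo_cols, expo_data = [], []
    n_binary = int(round(config.n_exposures * config.binary_exposure_fraction))
    for j in range(config.n_exposures):
        if j < n_binary:
            prev = rng.uniform(0.1, 0.5)
            col = _draw_nonconstant(rng, lambda r: r.binomial(1, prev, n).astype(float))
        else:
            col = rng.standard_normal(n)
        expo_cols.append(f"E{j + 1:02d}")
        expo_data.append(col)
    exposome = pd.DataFrame(np.column_stack(expo_data), index=sample_ids, columns=expo_cols)

    # ---- locus layout -----------------------------------------------------
    classes = [c for c in ALL_CLASSES for _ in range(config.loci_per_class.get(c, 0))]
    rng.shuffle(classes)
    n_loci = len(classes)
    loci: list[Locus] = []
    snp_rows = []  # (snp_id, chrom, pos)
    probe_rows = []  # (probe_id, chrom, pos)
    probe_idx = snp_idx = 0
    per_chrom = int(np.ceil(n_loci / config.n_chromosomes)) if n_loci else 1

    for li, cls in enumerate(classes):
        chrom = f"chr{li // per_chrom + 1}"
        center = 1_500_000 + (li % per_chrom) * config.locus_spacing
        is_vmr = rng.random() < config.vmr_fraction
        if is_vmr:
            m = int(rng.integers(config.vmr_probe_range[0], config.vmr_probe_range[1] + 1))
            gaps = rng.integers(50, 801, size=m - 1)
            positions = center + np.concatenate([[0], np.cumsum(gaps)])
        else:
            m = 1
            positions = np.array([center])
        pids = []
        for p in positions:
            pid = f"cg{probe_idx:06d}"
            probe_rows.append((pid, chrom, int(p)))
            pids.append(pid)
            probe_idx += 1
        sids = []
        for _ in range(config.cis_per_locus):
            sid = f"rs{snp_idx:06d}"
            pos = int(center + rng.integers(-900_000, 900_001))
            snp_rows.append((sid, chrom, max(1, pos)))
            sids.append(sid)
            snp_idx += 1
        loci.append(
            Locus(
                locus_id=f"locus{li:04d}",
                true_class=cls,
                kind="VMR" if is_vmr else "sVMP",
                chrom=chrom,
                positions=[int(p) for p in positions],
                probe_ids=pids,
                causal_snp=sorted(sids)[0] if sids else None,
            )
        )

    # filler probes in the gaps between locus blocks, isolated (>1 kb apart)
    n_planted_probes = probe_idx
    n_filler = max(0, int(round(config.hvp_fill_factor * n_planted_probes)) - n_planted_probes)
    filler_ids = []
    for i in range(n_filler):
        li = i % max(n_loci, 1)
        chrom = f"chr{li // per_chrom + 1}" if n_loci else "chr1"
        base = 1_500_000 + (li % per_chrom) * config.locus_spacing if n_loci else 1_500_000
        pos = base + 20_000 + (i // max(n_loci, 1)) * 2_500
        pid = f"cg{probe_idx:06d}"
        probe_rows.append((pid, chrom, int(pos)))
        filler_ids.append(pid)
        probe_idx += 1

    probe_manifest = _check_manifest(
        pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"]), "probe_id"
    )
    snp_manifest = _check_manifest(
        pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"]), "snp_id"
    )

    # ---- genotypes --------------------------------------------------------
    snp_ids = [r[0] for r in snp_rows]
    geno_cols = {}
    for sid in snp_ids:
        maf = rng.uniform(*config.maf_range)
        geno_cols[sid] = _draw_nonconstant(
            rng, lambda r: r.binomial(2, maf, n).astype(float)
        )
    genotypes = pd.DataFrame(geno_cols, index=sample_ids) if snp_ids else pd.DataFrame(
        index=sample_ids
    )

    # ---- methylation ------------------------------------------------------
    cov = covariates.to_numpy()
    meth = np.empty((n, probe_idx))
    col_of = {pid: i for i, (pid, _, _) in enumerate(probe_rows)}

    for locus in loci:
        m = len(locus.probe_ids)
        latent = config.latent_sd * rng.standard_normal(n)
        cbeta = rng.normal(0.0, config.covar_beta_sd, size=cov.shape[1])
        shared = cov @ cbeta + latent

        want = _n_terms(locus.true_class)
        terms: dict[str, np.ndarray] = {}
        if want["g"] or want["e"]:
            g = genotypes[locus.causal_snp].to_numpy() if want["g"] else None
            if want["e"]:
                locus.causal_exposure = expo_cols[int(rng.integers(len(expo_cols)))]
                e = exposome[locus.causal_exposure].to_numpy()
            else:
                e = None
            if want["g"]:
                terms["g"] = g - g.mean()
            if want["e"]:
                terms["e"] = e - e.mean()
            if want["gxe"]:
                t = (g - g.mean()) * (e - e.mean())
                design = np.column_stack([np.ones(n), g, e])
                coef, *_ = np.linalg.lstsq(design, t, rcond=None)
                terms["gxe"] = t - design @ coef
        if not want["g"]:
            locus.causal_snp = None

        n_t = len(terms)
        if n_t:
            w_m = _MEDIAN_VAR[min(m, 30) - 1]
            kappa = 1.0 + w_m * (1.0 - config.rho) / config.rho
            p_total = n_t * config.partial_r2
            if p_total * kappa >= 1.0:
                raise DataError(
                    f"infeasible partial R^2 targets for class {locus.true_class}: "
                    f"sum {p_total:.2f} (x{kappa:.2f} noise inflation) >= 1"
                )
            base_var = float(shared.var())
            signal = np.zeros(n)
            for name, t in terms.items():
                target_var = config.partial_r2 * kappa * base_var / (1.0 - p_total * kappa)
                beta = np.sqrt(target_var / t.var())
                locus.effect_sizes[name] = float(beta)
                signal += beta * t
            shared = shared + signal

        sigma_p = np.sqrt(shared.var() * (1.0 - config.rho) / config.rho)
        for pid in locus.probe_ids:
            mu = rng.normal(0.0, 2.0)
            meth[:, col_of[pid]] = mu + shared + sigma_p * rng.standard_normal(n)

    for pid in filler_ids:
        cbeta = rng.normal(0.0, config.covar_beta_sd, size=cov.shape[1])
        mu = rng.normal(0.0, 2.0)
        meth[:, col_of[pid]] = (
            mu + cov @ cbeta + config.filler_noise_sd * rng.standard_normal(n)
        )

    methylation = pd.DataFrame(
        meth, index=sample_ids, columns=[r[0] for r in probe_rows]
    )

    from .data_model import align

    dataset = align(
        methylation, genotypes, exposome, covariates, probe_manifest, snp_manifest
    )
    return dataset, loci


def null_config(
    n_vml: int = 200, n_samples: int = 300, seed: int = 0, **overrides
) -> SimConfig:
    """Global-null conditions: all loci class B, lean candidate pools."""
    kw = dict(
        n_samples=n_samples,
        loci_per_class={"B": n_vml},
        cis_per_locus=6,
        n_exposures=8,
        n_covariates=3,
        vmr_fraction=0.25,
        seed=seed,
    )
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def match_loci_to_vml(loci: list[Locus], vmls) -> dict[str, str | None]:
    """locus_id -> vml_id of the VML holding most of its probes (or None)."""
    probe_to_vml = {}
    for v in vmls:
        for p in v.probe_ids:
            probe_to_vml[p] = v.vml_id
    out = {}
    for locus in loci:
        hits = [probe_to_vml.get(p) for p in locus.probe_ids]
        hits = [h for h in hits if h is not None]
        if not hits:
            out[locus.locus_id] = None
        else:
            ids, counts = np.unique(hits, return_counts=True)
            out[locus.locus_id] = str(ids[np.argmax(counts)])
    return out


def evaluate_recovery(
    results: pd.DataFrame, loci: list[Locus], vmls
) -> dict:
    """Score final model calls against the planted truth.

    Returns a dict with a 5x5 confusion matrix (true class x called class; a
    locus whose probes ended up in no VML counts as called B), per-class
    sensitivity and precision, and — among correctly classified loci — the
    fraction whose winning model used the causal variables.
    """
    matched = match_loci_to_vml(loci, vmls)
    res = results.set_index("vml_id")
    confusion = pd.DataFrame(
        0, index=list(ALL_CLASSES), columns=list(ALL_CLASSES), dtype=int
    )
    causal_hits = causal_total = 0
    for locus in loci:
        vid = matched[locus.locus_id]
        called = "B"
        if vid is not None and vid in res.index:
            called = str(res.loc[vid, "winner_class"])
        confusion.loc[locus.true_class, called] += 1
        if called == locus.true_class and locus.true_class in INFORMATIVE_CLASSES:
            causal_total += 1
            snp_ok = locus.causal_snp is None or res.loc[vid, "snp_id"] == locus.causal_snp
            exp_ok = (
                locus.causal_exposure is None
                or res.loc[vid, "exposure_id"] == locus.causal_exposure
            )
            causal_hits += int(snp_ok and exp_ok)

    sens, prec = {}, {}
    for c in ALL_CLASSES:
        row = confusion.loc[c].sum()
        col = confusion[c].sum()
        sens[c] = confusion.loc[c, c] / row if row else np.nan
        prec[c] = confusion.loc[c, c] / col if col else np.nan
    return {
        "confusion": confusion,
        "sensitivity": sens,
        "precision": prec,
        "causal_recovery": causal_hits / causal_total if causal_total else np.nan,
    }


# ---------------------------------------------------------------------------
# file export (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_dataset(dataset: AlignedDataset, loci: list[Locus], outdir) -> None:
    """Write the simulated tables in the formats the pipeline reads, plus
    a ground-truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.methylation.to_csv(outdir / "methylation.tsv", sep="\t")
    dataset.genotypes.to_csv(outdir / "genotypes.tsv", sep="\t")
    dataset.exposome.to_csv(outdir / "exposome.tsv", sep="\t")
    dataset.covariates.to_csv(outdir / "covariates.tsv", sep="\t")
    dataset.probe_manifest.to_csv(outdir / "probe_manifest.tsv", sep="\t", index=False)
    dataset.snp_manifest.to_csv(outdir / "snp_manifest.tsv", sep="\t", index=False)
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump([asdict(l) for l in loci], fh, indent=1)
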