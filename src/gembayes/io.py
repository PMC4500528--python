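"""Tabular input/output, configuration and the misclassification sensitivity sweep.

Data dialect (documented once, used everywhere): one row per subject with
columns ``id`` (optional), ``D`` (0 = control), ``X`` (observed binary
exposure), optional covariates ``Z_*`` and one column per marker holding the
allele-M dosage 0/1/2 or NA for a missing call.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import MisclassSpec
from .genotype import MISSING
from .pseudolik import CaseControlData, FitResult
from .risk import StudyDesign

__all__ = [
    "read_case_control_table",
    "write_case_control_table",
    "data_to_frame",
    "fit_result_to_json",
    "load_run_config",
    "save_risk_params",
    "load_risk_params",
    "sensitivity_sweep",
    "vcf_to_genotype_table",
    "write_manifest",
]

_RESERVED = {"id", "D", "X"}

_CONFIG_KEYS = {
    "data",
    "model_kind",
    "xi0",
    "xi1",
    "xi_grid",
    "prevalence",
    "prior_sd",
    "prior_mean",
    "ld_prior",
    "n_iter",
    "burn_in",
    "seed",
    "output_dir",
    "covariate_cols",
}


class SchemaError(ValueError):
    """A table or configuration violated the documented schema."""


def read_case_control_table(
    path: str | Path,
    prevalence: float | None = None,
    sep: str | None = None,
) -> CaseControlData:
    """Read and validate a case-control CSV/TSV table.

    Errors name the offending row (0-based data row) and column.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("D", "X"):
        if col not in df.columns:
            raise SchemaError(f"required column '{col}' is missing")
    z_cols = [c for c in df.columns if c.startswith("Z_")]
    marker_cols = [c for c in df.columns if c not in _RESERVED and c not in z_cols]
    if not marker_cols:
        raise SchemaError("no marker columns found")
    x = df["X"].to_numpy()
    bad = np.where(~np.isin(x, [0, 1]))[0]
    if bad.size:
        raise SchemaError(f"non-binary X at row {bad[0]} (value {x[bad[0]]!r})")
    g = df[marker_cols].to_numpy(dtype=float)
    finite = ~np.isnan(g)
    bad_mask = finite & ~np.isin(np.where(finite, g, 0), [0, 1, 2])
    if bad_mask.any():
        r, c = np.argwhere(bad_mask)[0]
        raise SchemaError(
            f"invalid genotype value {g[r, c]!r} at row {r}, column '{marker_cols[c]}'"
        )
    design = None
    if prevalence is not None:
        d = df["D"].to_numpy(dtype=int)
        design = StudyDesign([(d == 0).sum(), (d == 1).sum()], pi=[prevalence])
    return CaseControlData(
        d=df["D"].to_numpy(dtype=int),
        x=x.astype(int),
        g=g,
        z=df[z_cols].to_numpy(dtype=float) if z_cols else None,
        design=design,
        marker_names=marker_cols,
    )


def data_to_frame(data: CaseControlData) -> pd.DataFrame:
    names = list(data.marker_names or [f"m{j+1}" for j in range(data.n_markers)])
    g = data.g.astype(float)
    g[g == MISSING] = np.nan
    out = pd.DataFrame({"D": data.d, "X": data.x})
    if data.z is not None:
        for j in range(data.z.shape[1]):
            out[f"Z_{j+1}"] = data.z[:, j]
    for j, nm in enumerate(names):
        out[nm] = g[:, j]
    return out


def write_case_control_table(data: CaseControlData, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    data_to_frame(data).to_csv(path, sep=sep, index=False)


def fit_result_to_json(fit: FitResult) -> str:
    payload = {
        "estimates": fit.estimates.to_dict(),
        "se": fit.se.to_dict(),
        "loglik": fit.loglik,
        "converged": fit.converged,
        "message": fit.message,
        "grad_norm": None if np.isnan(fit.grad_norm) else fit.grad_norm,
    }
    return json.dumps(payload, indent=2, default=float)


def load_run_config(path: str | Path) -> dict:
    """YAML run configuration; unknown keys are rejected before any compute."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("configuration must be a mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
    return cfg


def save_risk_params(params, path: str | Path) -> None:
    """Write risk coefficients to a flat key-value file (JSON or YAML).

    Each coefficient block appears under its own key; floats are written
    with Python's shortest round-tripping representation, so a JSON
    save/load cycle is bit-exact.
    """
    from .risk import RiskParams  # noqa: F401 - documented return type

    payload: dict = {"model_kind": params.model_kind}
    payload["beta0"] = params.beta0.tolist()
    if params.kappa is not None:
        payload["kappa"] = params.kappa.tolist()
    payload["beta_t"] = params.beta_t.tolist()
    for name in ("beta_z", "beta_a", "beta_at", "beta_az",
                 "beta_d", "beta_dt", "beta_dz"):
        block = getattr(params, name)
        if block is not None:
            payload[name] = np.asarray(block).tolist()
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_risk_params(path: str | Path):
    """Inverse of :func:`save_risk_params`."""
    from .risk import RiskParams

    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    return RiskParams(**payload)


def write_manifest(out_dir: str | Path, config: dict, seed: int | None) -> Path:
    """Reproducibility manifest: config hash, seed and package versions."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "gembayes": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def sensitivity_sweep(
    data: CaseControlData,
    grid: list[tuple[float, float]],
    model_kind: str = "gem",
    pi_known: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Refit the pseudo-MLE over a grid of assumed (xi0, xi1) values.

    Long-format result with one row per (grid cell, parameter); the
    ``significant`` flag (Wald test at ``alpha``) supports spotting
    parameters whose inference flips across plausible misclassification
    settings.  Per-cell failures are recorded, never fatal.
    """
    from scipy.stats import norm

    from .pseudolik import fit_pseudo_mle

    if not grid:
        raise ValueError("sensitivity grid must be nonempty")
    zcrit = norm.ppf(1 - alpha / 2)
    rows = []
    for xi0, xi1 in grid:
        try:
            fit = fit_pseudo_mle(
                data, MisclassSpec(xi0=xi0, xi1=xi1), model_kind=model_kind,
                pi_known=pi_known,
            )
            for name, est in fit.estimates.items():
                se = fit.se[name]
                rows.append(
                    {
                        "xi0": xi0,
                        "xi1": xi1,
                        "parameter": name,
                        "estimate": est,
                        "se": se,
                        "significant": bool(abs(est) > zcrit * se) if np.isfinite(se) and se > 0 else None,
                        "error": "",
                    }
                )
        except Exception as exc:
            rows.append(
                {"xi0": xi0, "xi1": xi1, "parameter": None, "estimate": np.nan,
                 "se": np.nan, "significant": None, "error": str(exc)}
            )
    out = pd.DataFrame(rows)
    flips = (
        out.dropna(subset=["parameter"])
        .groupby("parameter")["significant"]
        .nunique(dropna=True)
    )
    out.attrs["significance_flips"] = sorted(flips[flips > 1].index)
    return out


def vcf_to_genotype_table(vcf_path: str | Path, out_path: str | Path | None = None) -> pd.DataFrame:
    """Convert the GT field of a VCF to an allele-dosage table (ALT = allele M).

    Requires ``cyvcf2``.  Missing calls become NA; variants are columns named
    by ID (or CHROM:POS), samples are rows.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("the VCF converter requires cyvcf2") from exc
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        name = var.ID or f"{var.CHROM}:{var.POS}"
        # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=float)
        gt[gt == 2] = np.nan  # cyvcf2 codes UNKNOWN as 2, HOM_ALT as 3
        gt[gt == 3] = 2.0
        cols[name] = gt
    df = pd.DataFrame(cols, index=samples)
    if out_path is not None:
        df.to_csv(out_path)
    return df
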