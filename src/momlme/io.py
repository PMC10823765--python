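"""Delimited-text, NIfTI, and GIfTI input/output plus run configuration.

Design tables and outcome matrices are header-carrying delimited text
(tab for ``.tsv``, comma otherwise); categorical covariates are dummy-coded
with one reference level dropped per factor so the design stays full rank.
Image outcomes (4-D NIfTI volumes or GIfTI surface sets) are flattened to an
outcome matrix with the masking bookkeeping needed to write statistic maps
back out.  Numeric tables are written with 17 significant digits so values
round-trip exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model_core import ObservationFrame, OutcomeMatrix

__all__ = [
    "RunConfig",
    "read_design_table",
    "read_outcomes",
    "read_grm",
    "write_results",
    "write_dataset",
]

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Serializable description of one fitting run."""

    design: str
    outcomes: str
    out_dir: str
    grm: str | None = None
    random_effects: list[str] = field(default_factory=lambda: ["F", "S"])
    contrasts: dict = field(default_factory=dict)
    n_bins: int = 20
    estimator: str = "mom"
    bootstrap: int = 0
    iterations: int = 1
    seed: int | None = None
    standardize: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_design_table(path, family_col: str = "family_id", subject_col: str = "subject_id") -> ObservationFrame:
    """Read a design table into an observation frame.

    Requires the family and subject id columns; every remaining column
    becomes a covariate.  Non-numeric covariates are dummy-coded with the
    first level dropped as the reference.  An ``intercept`` column is not
    added automatically.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in (family_col, subject_col):
        if col not in df.columns:
            raise ValueError(f"design table is missing required column '{col}'")
    fam = df[family_col].astype(str).to_numpy()
    sub = df[subject_col].astype(str).to_numpy()
    cov = df.drop(columns=[family_col, subject_col])
    if cov.shape[1] == 0:
        raise ValueError("design table has no covariate columns")
    cat_cols = [c for c in cov.columns if not pd.api.types.is_numeric_dtype(cov[c])]
    if cat_cols:
        cov = pd.get_dummies(cov, columns=cat_cols, drop_first=True, dtype=np.float64)
    X = cov.to_numpy(dtype=np.float64)
    return ObservationFrame(
        subject_id=sub, family_id=fam, X=X, covariate_names=list(cov.columns)
    )


@dataclass
class ImageInfo:
    """Bookkeeping for mapping outcome columns back to image space."""

    kind: str                 # "nifti" | "gifti"
    mask: np.ndarray          # boolean over voxels/vertices (flattened)
    shape: tuple
    affine: np.ndarray | None = None


def read_outcomes(
    source,
    standardize: bool = False,
    mask=None,
) -> tuple[OutcomeMatrix, ImageInfo | None]:
    """Read an outcome matrix from delimited text or image files.

    ``source`` is a delimited-text path (N x J with header), a 4-D NIfTI
    path (time axis = observations; voxels masked to finite, non-constant
    columns, intersected with ``mask`` when given), or a list of GIfTI
    paths (one per observation, vertices as columns).  Returns the matrix
    and, for images, the info needed to write statistic maps.
    """
    info = None
    if isinstance(source, (list, tuple)):
        import nibabel as nib

        rows = []
        for pth in source:
            img = nib.load(str(pth))
            rows.append(np.concatenate([d.data.ravel() for d in img.darrays]))
        data = np.vstack(rows)
        keep = np.isfinite(data).all(axis=0) & (data.std(axis=0) > 0)
        info = ImageInfo(kind="gifti", mask=keep, shape=(data.shape[1],))
        Y = data[:, keep]
        names = [f"v{k}" for k in np.flatnonzero(keep)]
    elif str(source).endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(source))
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise ValueError("NIfTI outcomes must be 4-D (x, y, z, observation)")
        vox = data.reshape(-1, data.shape[3]).T  # N x voxels
        keep = np.isfinite(vox).all(axis=0) & (vox.std(axis=0) > 0)
        if mask is not None:
            keep &= np.asarray(mask, dtype=bool).ravel()
        info = ImageInfo(
            kind="nifti", mask=keep, shape=data.shape[:3], affine=img.affine
        )
        Y = vox[:, keep]
        names = [f"v{k}" for k in np.flatnonzero(keep)]
    else:
        df = pd.read_csv(source, sep=_sep_for(source))
        const = df.columns[df.std(axis=0) == 0]
        if len(const):
            warnings.warn(
                f"dropping {len(const)} all-constant outcome column(s)", stacklevel=2
            )
            df = df.drop(columns=const)
        Y = df.to_numpy(dtype=np.float64)
        names = list(df.columns)
    if not np.all(np.isfinite(Y)):
        raise ValueError("outcome matrix contains missing or non-finite values")
    standardized = False
    if standardize:
        Y = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=0)
        standardized = True
    return OutcomeMatrix(Y=Y, outcome_names=names, standardized=standardized), info


def read_grm(path, frame: ObservationFrame) -> sp.csr_matrix:
    """Read a square relatedness matrix keyed by subject ids.

    The file is delimited text whose header row and first column hold
    subject ids; the matrix is expanded to observation order (repeated
    observations of one subject share its relatedness entries).
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    subs = np.unique(frame.subject_id.astype(str))
    missing = set(subs) - set(df.index)
    if missing:
        raise ValueError(f"GRM is missing subjects: {sorted(missing)[:5]}")
    K_sub = df.loc[subs, subs].to_numpy(dtype=np.float64)
    pos = {s: k for k, s in enumerate(subs)}
    idx = np.array([pos[s] for s in frame.subject_id.astype(str)])
    return sp.csr_matrix(K_sub[np.ix_(idx, idx)])


def write_dataset(out_dir, frame: ObservationFrame, outcomes: OutcomeMatrix) -> None:
    """Dump a dataset to the design/outcome text formats the CLI consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(frame.X, columns=frame.covariate_names)
    df.insert(0, "subject_id", frame.subject_id)
    df.insert(0, "family_id", frame.family_id)
    df.to_csv(out / "design.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(outcomes.Y, columns=outcomes.outcome_names).to_csv(
        out / "outcomes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )


def write_results(result, components, config: RunConfig | None, out_dir, image_info=None, ci=None) -> list[str]:
    """Write fixed-effect, contrast, and variance-component tables.

    One row per (outcome, covariate) with beta, se, z, and -log10 p; a
    per-outcome component table with normalized fractions and the total
    residual variance; optional bootstrap CI table; optional NIfTI/GIfTI
    statistic maps when the outcomes came from images.  Returns the paths
    written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    p, J = result.beta.shape
    with np.errstate(divide="ignore"):
        nlp = -np.log10(result.p_value)
    rows = pd.DataFrame(
        {
            "outcome": np.repeat(result.outcome_names, p),
            "covariate": np.tile(result.covariate_names, J),
            "beta": result.beta.T.ravel(),
            "se": result.se.T.ravel(),
            "z": result.z.T.ravel(),
            "neg_log10_p": nlp.T.ravel(),
        }
    )
    path = out / "fixed_effects.tsv"
    rows.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(str(path))

    comp = pd.DataFrame(components.theta.T, columns=components.labels)
    comp.insert(0, "outcome", result.outcome_names)
    comp["sigma2_total"] = components.sigma2_total
    path = out / "variance_components.tsv"
    comp.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    written.append(str(path))

    if ci is not None:
        ci_rows = []
        for e, lab in enumerate(components.labels):
            for jcol, name in enumerate(result.outcome_names):
                ci_rows.append(
                    {
                        "outcome": name,
                        "component": lab,
                        "point": components.theta[e, jcol],
                        "lower": ci.lower[e, jcol],
                        "upper": ci.upper[e, jcol],
                    }
                )
        path = out / "component_ci.tsv"
        pd.DataFrame(ci_rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(str(path))

    if config is not None:
        path = out / "config.yaml"
        config.to_yaml(path)
        written.append(str(path))

    if image_info is not None:
        written.extend(_write_maps(result, image_info, out))
    return written


def _write_maps(result, info, out: Path, fill: float = 0.0) -> list[str]:
    import nibabel as nib

    written = []
    for k, name in enumerate(result.covariate_names):
        for stat, arr in (("z", result.z[k]), ("beta", result.beta[k])):
            flat = np.full(int(np.prod(info.shape)), fill)
            flat[np.flatnonzero(info.mask)] = arr
            safe = str(name).replace("/", "_")
            if info.kind == "nifti":
                img = nib.Nifti1Image(
                    flat.reshape(info.shape).astype(np.float32), info.affine
                )
                path = out / f"map_{safe}_{stat}.nii.gz"
                nib.save(img, str(path))
            else:
                da = nib.gifti.GiftiDataArray(flat.astype(np.float32))
                img = nib.gifti.GiftiImage(darrays=[da])
                path = out / f"map_{safe}_{stat}.gii"
                nib.save(img, str(path))
            written.append(str(path))
    return written
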