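"""File I/O: delimited-table readers, model and summary serialization.

Clinical and genomic tables are CSV/TSV with a header row and the sample ID
in the first column; the two files are merged on sample IDs (clinical-file
order, restricted to the intersection), never on row order.  Fitted models
round-trip through JSON exactly: loading a saved model reproduces its
predictions to machine precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import estimators as _est

logger = logging.getLogger("lspls")


@dataclass
class ClinicoGenomicDataset:
    """Aligned outcome / clinical / genomic triple read from files."""

    Y: np.ndarray
    D: np.ndarray
    X: np.ndarray
    sample_ids: list[str]
    clinical_names: list[str]
    genomic_names: list[str]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def read_dataset(clinical_path, genomic_path, outcome_column: str) -> ClinicoGenomicDataset:
    """Load and align a clinical table (containing the outcome) and a genomic table.

    Rows are matched on sample IDs; unmatched IDs are dropped with a logged
    report.  The outcome column must be coded 0/1 and all remaining cells
    must be numeric.
    """
    clin = _read_table(clinical_path)
    geno = _read_table(genomic_path)
    if outcome_column not in clin.columns:
        raise ValueError(
            f"outcome column {outcome_column!r} not found in {clinical_path}"
        )
    common = [sid for sid in clin.index if sid in set(geno.index)]
    if not common:
        raise ValueError("no sample IDs shared between the clinical and genomic files")
    dropped = sorted(set(clin.index).symmetric_difference(geno.index))
    if dropped:
        logger.warning("dropped %d unmatched sample IDs: %s", len(dropped), dropped[:10])
    clin = clin.loc[common]
    geno = geno.loc[common]

    y_raw = clin[outcome_column]
    for sid, val in y_raw.items():
        if val not in (0, 1):
            raise ValueError(
                f"outcome must be coded 0/1; sample {sid!r} has value {val!r}"
            )
    Y = y_raw.to_numpy(dtype=int)
    D_df = clin.drop(columns=[outcome_column])
    try:
        D = D_df.to_numpy(dtype=float)
        X = geno.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in input tables: {exc}") from exc
    if np.isnan(D).any() or np.isnan(X).any():
        raise ValueError("missing values are not supported")
    return ClinicoGenomicDataset(
        Y=Y, D=D, X=X, sample_ids=list(common),
        clinical_names=list(D_df.columns), genomic_names=list(geno.columns),
    )


# --- model serialization ----------------------------------------------------

def _encode(obj):
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _decode(d):
    if "__ndarray__" in d:
        return np.asarray(d["__ndarray__"], dtype=d["dtype"])
    return d


def _fit_state(model) -> dict:
    """Collect the fitted state of an estimator (public *_ attributes plus the
    private projection machinery each class needs to score new samples)."""
    from .pls import LSPLSFit

    state = {}
    for name in vars(model):
        if name.endswith("_") and not name.startswith("_"):
            state[name] = getattr(model, name)
    extra = {}
    lspls = getattr(model, "_lspls", None)
    if lspls is not None:
        extra["_lspls"] = {
            "gamma_Dtilde": lspls.gamma_Dtilde, "gamma_X": lspls.gamma_X,
            "gamma_T": lspls.gamma_T, "V": lspls.V, "T": lspls.T,
            "proj_C": lspls.proj_C, "kappa": lspls.kappa,
            "n_effective": lspls.n_effective,
        }
    if hasattr(model, "_proj_C"):
        extra["_proj_C"] = model._proj_C
    if hasattr(model, "_x_center"):
        extra["_x_center"] = model._x_center
    state["__extra__"] = extra
    return state


def save_model(model, path) -> None:
    """Serialize a fitted estimator to JSON."""
    payload = {
        "class": type(model).__name__,
        "method": model.method,
        "params": model.get_params(),
        "state": _fit_state(model),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_encode)


def load_model(path):
    """Reconstruct a fitted estimator saved by :func:`save_model`."""
    from .pls import LSPLSFit

    with open(path) as fh:
        payload = json.load(fh, object_hook=_decode)
    cls = getattr(_est, payload["class"])
    model = cls(**payload["params"])
    state = payload["state"]
    extra = state.pop("__extra__", {})
    for name, value in state.items():
        setattr(model, name, value)
    if "_lspls" in extra:
        d = extra["_lspls"]
        model._lspls = LSPLSFit(
            gamma_Dtilde=d["gamma_Dtilde"], gamma_X=d["gamma_X"],
            gamma_T=d["gamma_T"], V=d["V"], T=d["T"], proj_C=d["proj_C"],
            kappa=int(d["kappa"]), n_effective=int(d["n_effective"]),
        )
    if "_proj_C" in extra:
        model._proj_C = extra["_proj_C"]
    if "_x_center" in extra:
        model._x_center = extra["_x_center"]
    return model


def write_summary(summary, out_dir) -> None:
    """Write the tidy per-replicate table and the aggregate tables as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary.table.to_csv(out / "replicates.csv", index=False)
    summary.convergence_table().to_csv(out / "convergence_rates.csv")
    summary.summary_table().to_csv(out / "summary.csv", index=False)


def write_dataset(ds, out_dir, prefix: str = "") -> None:
    """Write a synthetic replicate as CSV tables plus a JSON config sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for split in ("train", "test"):
        D = getattr(ds, f"D_{split}")
        X = getattr(ds, f"X_{split}")
        Y = getattr(ds, f"Y_{split}")
        ids = [f"{split}_{i}" for i in range(len(Y))]
        clin = pd.DataFrame(D, index=ids,
                            columns=[f"d{j+1}" for j in range(D.shape[1])])
        clin.insert(0, "outcome", Y)
        clin.rename_axis("sample_id").to_csv(out / f"{prefix}clinical_{split}.csv")
        pd.DataFrame(
            X, index=ids, columns=[f"x{j+1}" for j in range(X.shape[1])]
        ).rename_axis("sample_id").to_csv(out / f"{prefix}genomic_{split}.csv")
    sidecar = {
        "config": ds.config.to_dict() if ds.config is not None else None,
        "replicate_id": ds.replicate_id,
        "gamma_intercept": ds.gamma_intercept,
        "gamma_D": ds.gamma_D,
        "gamma_X": ds.gamma_X,
    }
    with open(out / f"{prefix}config.json", "w") as fh:
        json.dump(sidecar, fh, default=_encode)
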