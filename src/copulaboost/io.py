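"""Dataset and configuration I/O, fit serialization.

Datasets are delimited text files with a header.  A schema declares the
response columns and their kinds so typing errors are caught with row
numbers before any computation.  Fits are stored as human-readable JSON
with a SHA-256 checksum line; loading verifies the checksum and the format
version and reconstructs a prediction-capable fit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .bivlik import BivariateCopulaModel, UnivariateModel
from .boost import BoostConfig, BoostFit
from .learners import BaseLearner, LearnerSpec

__all__ = [
    "load_dataset", "load_adjacency", "load_config",
    "model_from_config", "learner_specs_from_config",
    "save_fit", "load_fit",
]

FIT_FORMAT_VERSION = 1


def load_dataset(path, schema=None, sep=","):
    """Read a delimited dataset and validate declared response kinds.

    ``schema`` maps column name -> kind in {binary, count, continuous,
    region}.  Missing values are rejected (no imputation).
    """
    df = pd.read_csv(path, sep=sep)
    if df.isna().any().any():
        bad = df.index[df.isna().any(axis=1)][:5].tolist()
        raise ValueError(f"missing values in {path} (first rows: {bad}); imputation is not supported")
    for col, kind in (schema or {}).items():
        if col not in df.columns:
            raise ValueError(f"declared column '{col}' absent from {path}")
        vals = df[col]
        if kind == "binary":
            if not vals.isin([0, 1]).all():
                row = int(vals.index[~vals.isin([0, 1])][0])
                raise ValueError(f"column '{col}' must be binary 0/1; offending row {row}")
        elif kind == "count":
            arr = vals.to_numpy()
            ok = (arr >= 0) & (np.asarray(arr, float) == np.floor(np.asarray(arr, float)))
            if not ok.all():
                row = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"column '{col}' must hold non-negative integers; offending row {row}"
                )
        elif kind == "continuous":
            pd.to_numeric(vals)  # raises on junk
        elif kind == "region":
            df[col] = vals.astype(str)
        else:
            raise ValueError(f"unknown schema kind '{kind}'")
    return df


def load_adjacency(path):
    """Two-column edge list of region labels -> list of (a, b) pairs."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 2:
                raise ValueError(f"adjacency lines must have two labels: {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def load_config(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def model_from_config(cfg):
    """Build the model from the config's ``model`` block.

    Example::

        model:
          copula: clayton270
          margins:
            - {family: bernoulli, link: probit}
            - {family: gaussian_hetero}
          responses: [fever, wasting]
    """
    from .copulas import get_copula
    from .margins import get_margin

    blk = cfg["model"]
    mgs = []
    for m in blk["margins"]:
        if isinstance(m, str):
            mgs.append(get_margin(m))
        else:
            mgs.append(get_margin(m["family"], link=m.get("link")))
    model = BivariateCopulaModel(mgs[0], mgs[1], get_copula(blk["copula"]))
    responses = tuple(blk.get("responses", ("y1", "y2")))
    return model, responses


def learner_specs_from_config(cfg, model, covariates):
    """Per-parameter learner lists from the config's ``predictors`` block;
    falls back to intercept + linear on every covariate."""
    from .boost import default_learner_specs

    blk = cfg.get("predictors")
    if blk is None:
        return default_learner_specs(model, covariates)
    if "default" in blk:
        d = blk["default"]
        return default_learner_specs(
            model, covariates, kind=d.get("kind", "linear"),
            df=d.get("df", 4.0), knots=d.get("knots", 20),
        )
    specs = {}
    for k in range(model.K):
        key = str(k)
        if key not in blk and k not in blk:
            raise ValueError(f"predictors block missing parameter {k}")
        entries = blk.get(key, blk.get(k))
        ls = [LearnerSpec("intercept")]
        for e in entries:
            ls.append(LearnerSpec(
                e["kind"], tuple(e.get("covariates", ())), by=e.get("by"),
                knots=e.get("knots", 20), degree=e.get("degree", 3),
                penalty_order=e.get("penalty_order", 2), df=e.get("df", 4.0),
            ))
        specs[k] = ls
    return specs


def boost_config_from_config(cfg, seed=None, mstop_max=None, step_length=None):
    blk = dict(cfg.get("boost", {}))
    if seed is not None:
        blk["seed"] = seed
    if mstop_max is not None:
        blk["mstop_max"] = mstop_max
    if step_length is not None:
        blk["step_length"] = step_length
    return BoostConfig(**blk)


# ---------------------------------------------------------------------------
# Fit serialization
# ---------------------------------------------------------------------------


def _model_meta(model):
    if isinstance(model, UnivariateModel):
        return {"kind": "univariate", "margin": model.margin.name}
    rot = str(model.copula.rotation) if model.copula.rotation else ""
    return {
        "kind": "bivariate",
        "margin1": model.margin1.name,
        "margin1_link": model.margin1.links[0].name,
        "margin2": model.margin2.name,
        "copula": f"{model.copula.name}{rot}",
    }


def _model_from_meta(meta):
    from .copulas import get_copula
    from .margins import get_margin

    if meta["kind"] == "univariate":
        return UnivariateModel(meta["margin"])
    m1 = get_margin(meta["margin1"],
                    link=meta["margin1_link"] if meta["margin1"] == "bernoulli" else None)
    return BivariateCopulaModel(m1, get_margin(meta["margin2"]), get_copula(meta["copula"]))


def save_fit(fit: BoostFit, path):
    payload = {
        "format_version": FIT_FORMAT_VERSION,
        "model": _model_meta(fit.model),
        "config": asdict(fit.config),
        "offsets": fit.offsets.tolist(),
        "mstop_opt": fit.mstop_opt,
        "risk_offset_train": fit.risk_offset_train,
        "risk_offset_val": None if np.isnan(fit.risk_offset_val) else fit.risk_offset_val,
        "learners": {str(k): [bl.to_dict() for bl in bls] for k, bls in fit.learners.items()},
        "updates": [[k, j, inc.tolist()] for k, j, inc in fit.updates],
        "history": fit.history.to_dict(orient="list") if fit.history is not None else None,
    }
    body = json.dumps(payload, sort_keys=True)
    digest = hashlib.sha256(body.encode()).hexdigest()
    with open(path, "w") as fh:
        fh.write(body + "\n" + digest + "\n")
    return path


def load_fit(path) -> BoostFit:
    with open(path) as fh:
        body = fh.readline().rstrip("\n")
        digest = fh.readline().strip()
    if hashlib.sha256(body.encode()).hexdigest() != digest:
        raise ValueError(f"fit file {path} failed its checksum; refusing to load")
    payload = json.loads(body)
    if payload["format_version"] != FIT_FORMAT_VERSION:
        raise ValueError(
            f"fit format version {payload['format_version']} != {FIT_FORMAT_VERSION}"
        )
    model = _model_from_meta(payload["model"])
    learners = {
        int(k): [BaseLearner.from_dict(d) for d in bls]
        for k, bls in payload["learners"].items()
    }
    fit = BoostFit(
        model=model,
        config=BoostConfig(**payload["config"]),
        offsets=np.asarray(payload["offsets"], float),
        learners=learners,
        updates=[(k, j, np.asarray(inc, float)) for k, j, inc in payload["updates"]],
        history=pd.DataFrame(payload["history"]) if payload["history"] is not None else None,
        mstop_opt=payload["mstop_opt"],
        risk_offset_train=payload["risk_offset_train"],
        risk_offset_val=payload["risk_offset_val"] if payload["risk_offset_val"] is not None else np.nan,
    )
    return fit
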