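"""Readers, writers and run configuration.

Canonical interchange formats (documented in FORMATS.md): long-format
ratings CSV with header ``ratee,item,rater,score``; Q-matrix CSV with a
header of attribute names and one 0/1 row per item; YAML run
configuration; JSON posterior summaries.  External ratee/item/rater ids
are opaque strings mapped to dense indices on read; the mapping is kept on
the table and persisted next to results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mcmc import ChainSchedule, ModelSpec, PosteriorSummary, PriorSpec
from .simulate import RatingsTable

RATINGS_COLUMNS = ["ratee", "item", "rater", "score"]


def read_ratings(path) -> RatingsTable:
    """Read and validate a long-format ratings CSV.

    Scores must be 0/1 and (ratee, item, rater) triples unique; failures
    name the offending line (1-based, counting the header).
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RATINGS_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    scores = pd.to_numeric(frame["score"], errors="coerce")
    bad = np.flatnonzero(~scores.isin([0, 1]).to_numpy())
    if bad.size:
        raise ValueError(
            f"{path}: non-binary score at line {bad[0] + 2} "
            f"(value {frame['score'].iloc[bad[0]]!r})")
    dup = frame.duplicated(RATINGS_COLUMNS[:3])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0])
        triple = frame.iloc[line][RATINGS_COLUMNS[:3]].tolist()
        raise ValueError(f"{path}: duplicate (ratee, item, rater) triple {triple} "
                         f"at line {line + 2}")

    id_maps: dict[str, dict[str, int]] = {}
    dense = {}
    for col in RATINGS_COLUMNS[:3]:
        values = frame[col].to_numpy()
        uniques = pd.unique(values)
        try:  # numeric ids keep numeric order; otherwise lexicographic
            order = np.argsort(pd.to_numeric(pd.Series(uniques)).to_numpy())
        except (ValueError, TypeError):
            order = np.argsort(uniques)
        mapping = {str(u): i for i, u in enumerate(uniques[order])}
        id_maps[col] = mapping
        dense[col] = np.array([mapping[str(v)] for v in values], dtype=np.int64)
    records = pd.DataFrame({**dense, "score": scores.astype(np.int8).to_numpy()})
    return RatingsTable(records,
                        n_ratees=len(id_maps["ratee"]), n_items=len(id_maps["item"]),
                        n_raters=len(id_maps["rater"]), id_maps=id_maps)


def write_ratings(table: RatingsTable, path) -> None:
    table.records[RATINGS_COLUMNS].to_csv(path, index=False)


def write_truth(table: RatingsTable, directory) -> list[Path]:
    """Persist the generating truth (profiles, θ, ξ) as sidecar CSVs."""
    directory = Path(directory)
    written = []
    if table.true_profiles is not None:
        p = directory / "truth_profiles.csv"
        pd.DataFrame(table.true_profiles,
                     columns=[f"A{k + 1}" for k in range(table.true_profiles.shape[1])]
                     ).to_csv(p, index_label="ratee")
        written.append(p)
    if table.true_theta is not None:
        p = directory / "truth_theta.csv"
        pd.DataFrame(table.true_theta).to_csv(p, index_label="ratee")
        written.append(p)
    if table.true_xi is not None:
        p = directory / "truth_xi.csv"
        pd.DataFrame(table.true_xi).to_csv(p, index_label="ratee")
        written.append(p)
    return written


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run (logged before computing)."""

    model: str = "facets"
    cdm: str = "saturated"
    qmatrix: str | None = None
    ratings: str | None = None
    output_dir: str = "."
    seed: int = 0
    schedule: ChainSchedule = field(default_factory=ChainSchedule)
    priors: PriorSpec = field(default_factory=PriorSpec)

    def spec(self) -> ModelSpec:
        return ModelSpec(self.model, self.cdm)

    def to_dict(self) -> dict:
        return {
            "model": self.model, "cdm": self.cdm, "qmatrix": self.qmatrix,
            "ratings": self.ratings, "output_dir": self.output_dir,
            "seed": self.seed,
            "schedule": {"n_chains": self.schedule.n_chains,
                         "n_iterations": self.schedule.n_iterations,
                         "burn_in": self.schedule.burn_in,
                         "thin": self.schedule.thin},
            "priors": {"item_sd": self.priors.item_sd,
                       "eta_sd": self.priors.eta_sd,
                       "phi_sd": self.priors.phi_sd,
                       "log_psi_sd": self.priors.log_psi_sd},
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schedule = ChainSchedule(**raw.pop("schedule", {}))
    priors = PriorSpec(**raw.pop("priors", {}))
    return RunConfig(schedule=schedule, priors=priors, **raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def summary_to_dict(summary: PosteriorSummary) -> dict:
    """JSON-ready posterior summary: EAP, posterior SD and R-hat per parameter,
    plus a rater block mirroring the severity/variability layout."""
    eap = summary.eap
    sd = summary.posterior_sd
    rhat = summary.rhat
    params = {name: {"eap": float(e), "sd": float(s), "rhat": float(r)}
              for name, e, s, r in zip(summary.param_names, eap, sd, rhat)}
    raters: dict[str, dict] = {}
    for name, entry in params.items():
        for prefix, label in (("eta[", "severity"), ("phi[", "severity"),
                              ("psi[", "variability")):
            if name.startswith(prefix):
                rater_id = name[len(prefix):-1]
                raters.setdefault(rater_id, {})[label] = entry["eap"]
                raters.setdefault(rater_id, {})[label + "_sd"] = entry["sd"]
    return {
        "model": {"rater_model": summary.spec.rater_model, "cdm": summary.spec.cdm},
        "seed": summary.seed,
        "parameters": params,
        "raters": raters,
        "acceptance": {k: float(v) for k, v in summary.acceptance.items()},
        "max_rhat": float(np.nanmax(rhat)) if len(rhat) else None,
        "n_free_params": summary.n_free_params,
        "mastery_probs": np.asarray(summary.mastery_probs).round(6).tolist(),
    }


def write_results(summary: PosteriorSummary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=1)


def write_draws(summary: PosteriorSummary, path) -> None:
    """Persist retained structural draws as CSV (chain, draw, then one column per parameter)."""
    n_chains, n_ret, _ = summary.draws.shape
    frame = pd.DataFrame(summary.flat_draws, columns=summary.param_names)
    frame.insert(0, "chain", np.repeat(np.arange(n_chains), n_ret))
    frame.insert(1, "draw", np.tile(np.arange(n_ret), n_chains))
    frame.to_csv(path, index=False)
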