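"""CSV / YAML serialization for panels, draw sets and configurations.

Long-format panel CSV columns: ``individual``, ``situation``,
``alternative``, ``chosen`` (0/1), then any attribute columns.  Draw-set CSV
columns: ``individual``, ``draw_index``, then one column per dimension named
after the mixed parameter it serves.  Configurations travel as YAML
key-value text.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from .mmnl_core import ChoicePanel, MixingParams
from .qmc_draws import DrawConfig, NormalDrawSet
from .synthetic_data import SimSpec

__all__ = [
    "panel_to_frame",
    "panel_from_frame",
    "write_panel_csv",
    "read_panel_csv",
    "draws_to_frame",
    "draws_from_frame",
    "config_to_yaml",
    "config_from_yaml",
    "params_to_yaml",
    "params_from_yaml",
    "simspec_to_yaml",
    "simspec_from_yaml",
    "config_digest",
]


def panel_to_frame(panel: ChoicePanel) -> pd.DataFrame:
    """Long-format frame, one row per (individual, situation, alternative)."""
    rows = []
    for i, chosen in enumerate(panel.chosen):
        for t, c in enumerate(chosen):
            for j in range(panel.n_alts):
                row = {
                    "individual": i,
                    "situation": t,
                    "alternative": panel.alt_labels[j],
                    "chosen": int(j == c),
                }
                if panel.attributes is not None:
                    for k, name in enumerate(
                        panel.attr_names
                        or [f"attr_{k+1}" for k in range(panel.attributes[i].shape[-1])]
                    ):
                        row[name] = panel.attributes[i][t, j, k]
                rows.append(row)
    return pd.DataFrame(rows)


def panel_from_frame(
    frame: pd.DataFrame, base_alternative: str | int = 0
) -> ChoicePanel:
    """Rebuild a :class:`ChoicePanel` from its long-format frame."""
    labels = list(dict.fromkeys(frame["alternative"]))
    label_idx = {lab: j for j, lab in enumerate(labels)}
    if isinstance(base_alternative, str):
        base = label_idx[base_alternative]
    else:
        base = int(base_alternative)
    attr_cols = [
        c
        for c in frame.columns
        if c not in ("individual", "situation", "alternative", "chosen")
    ]
    chosen, attrs = [], []
    for _, ind in frame.groupby("individual", sort=True):
        t_chosen, t_attrs = [], []
        for _, sit in ind.groupby("situation", sort=True):
            sit = sit.set_index("alternative").loc[labels]
            picked = np.flatnonzero(sit["chosen"].to_numpy())
            if picked.size != 1:
                raise ValueError(
                    "each situation must have exactly one chosen alternative"
                )
            t_chosen.append(picked[0])
            if attr_cols:
                t_attrs.append(sit[attr_cols].to_numpy())
        chosen.append(np.array(t_chosen))
        if attr_cols:
            attrs.append(np.stack(t_attrs))
    return ChoicePanel(
        chosen=tuple(chosen),
        n_alts=len(labels),
        base_alt=base,
        alt_labels=tuple(str(lab) for lab in labels),
        attributes=tuple(attrs) if attr_cols else None,
        attr_names=tuple(attr_cols),
    )


def write_panel_csv(panel: ChoicePanel, path) -> None:
    panel_to_frame(panel).to_csv(path, index=False)


def read_panel_csv(path, base_alternative: str | int = 0) -> ChoicePanel:
    return panel_from_frame(pd.read_csv(path), base_alternative)


def draws_to_frame(draws: NormalDrawSet) -> pd.DataFrame:
    c = draws.config
    i_idx, r_idx = np.meshgrid(
        np.arange(c.n_individuals), np.arange(c.draws_per_individual),
        indexing="ij",
    )
    data = {"individual": i_idx.ravel(), "draw_index": r_idx.ravel()}
    for k, name in enumerate(c.dim_names):
        data[name] = draws.points[:, :, k].ravel()
    return pd.DataFrame(data)


def draws_from_frame(frame: pd.DataFrame, config: DrawConfig) -> NormalDrawSet:
    pts = np.empty(
        (config.n_individuals, config.draws_per_individual, config.n_dims)
    )
    frame = frame.sort_values(["individual", "draw_index"])
    for k, name in enumerate(config.dim_names):
        pts[:, :, k] = (
            frame[name]
            .to_numpy()
            .reshape(config.n_individuals, config.draws_per_individual)
        )
    return NormalDrawSet(points=pts, config=config)


def config_to_yaml(config: DrawConfig) -> str:
    d = asdict(config)
    d["primes"] = list(d["primes"])
    d["dim_names"] = list(d["dim_names"])
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> DrawConfig:
    d = yaml.safe_load(text)
    d["primes"] = tuple(d["primes"])
    d["dim_names"] = tuple(d.get("dim_names") or ())
    return DrawConfig(**d)


def params_to_yaml(params: MixingParams) -> str:
    d = {
        "means": [float(m) for m in params.means],
        "chol": [[float(v) for v in row] for row in params.chol],
        "mixed_alts": list(params.mixed_alts),
        "fixed_asc": {int(k): float(v) for k, v in params.fixed_asc.items()},
    }
    if params.fixed_coeffs is not None:
        d["fixed_coeffs"] = [float(v) for v in params.fixed_coeffs]
    return yaml.safe_dump(d, sort_keys=True)


def params_from_yaml(text: str) -> MixingParams:
    d = yaml.safe_load(text)
    return MixingParams(
        means=np.asarray(d["means"], float),
        chol=np.asarray(d["chol"], float),
        mixed_alts=tuple(d["mixed_alts"]),
        fixed_asc={int(k): float(v) for k, v in d.get("fixed_asc", {}).items()},
        fixed_coeffs=(
            np.asarray(d["fixed_coeffs"], float) if "fixed_coeffs" in d else None
        ),
    )


def simspec_to_yaml(spec: SimSpec) -> str:
    d = asdict(spec)
    d["mixing_means"] = list(d["mixing_means"])
    d["mixing_cov"] = [list(row) for row in d["mixing_cov"]]
    return yaml.safe_dump(d, sort_keys=True)


def simspec_from_yaml(text: str) -> SimSpec:
    d = yaml.safe_load(text)
    d["mixing_means"] = tuple(d["mixing_means"])
    d["mixing_cov"] = tuple(map(tuple, d["mixing_cov"]))
    return SimSpec(**d)


def config_digest(text: str) -> str:
    """Short stable hash identifying a serialized configuration."""
    return hashlib.sha256(text.encode()).hexdigest()[:12]
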