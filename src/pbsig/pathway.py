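"""Pathway activity scoring by signature projection.

A pathway's in-vitro perturbation experiment (control vs pathway-activated
samples) trains the same metagene probit model used for the exposure
signatures; projecting the in-vivo study samples through that model gives
each animal a predicted probability of pathway activation.  Because
training and test data can sit on different array platforms, the test
matrix is first translated through a probe-bridging map (duplicates
averaged) and both matrices are restricted to their common probes; by
default every probe is then z-scored within training and within test
separately, which removes platform- and cohort-level location/scale
differences.

Group differences in predicted probability are assessed with one-way
ANOVA followed by Bonferroni-adjusted pairwise t tests on the pooled
within-group variance.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats import BridgingMap, ExpressionMatrix, map_platform
from .signature import MetageneModel, fit_metagene_model, predict_matrix

__all__ = [
    "PathwayTrainingSet",
    "PathwayActivity",
    "GroupComparison",
    "score_pathway",
    "one_way_anova_bonferroni",
]


@dataclasses.dataclass
class PathwayTrainingSet:
    """A named perturbation experiment: expression + binary activation labels."""

    name: str
    matrix: ExpressionMatrix
    labels: np.ndarray  # 0 = control, 1 = activated

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if np.unique(self.labels).size < 2:
            raise ValueError("training set needs both classes")


@dataclasses.dataclass
class PathwayActivity:
    """Per-sample activation probabilities for one pathway."""

    pathway: str
    table: pd.DataFrame  # sample_id, group, probability
    model: MetageneModel | None = None

    def group_means(self) -> pd.Series:
        return self.table.groupby("group", sort=False)["probability"].mean()

    def save_tsv(self, path: str | Path) -> None:
        self.table.assign(pathway=self.pathway).to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class GroupComparison:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: list[dict]  # {group_a, group_b, t, p_raw, p_adjusted}

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1) + "\n")


def _zscore_rows(frame: pd.DataFrame) -> pd.DataFrame:
    mu = frame.mean(axis=1)
    sd = frame.std(axis=1, ddof=1)
    sd = sd.replace(0.0, 1.0)
    return frame.sub(mu, axis=0).div(sd, axis=0)


def score_pathway(
    training: PathwayTrainingSet,
    test: ExpressionMatrix,
    bridge: BridgingMap | None = None,
    k: int = 250,
    m: int = 2,
    mode: str = "map",
    seed: int = 0,
    standardize: bool = True,
) -> PathwayActivity:
    """Train on the perturbation set and score every test sample.

    k is capped at the number of common probes after translation.  With
    ``standardize`` (default) each probe is z-scored within training and
    within test separately before fitting and projection.
    """
    if bridge is not None:
        test = map_platform(test, bridge)
    common = [p for p in training.matrix.probe_ids if p in set(test.probe_ids)]
    if not common:
        raise ValueError("no probes shared between training and test matrices")
    k_eff = min(k, len(common))

    train_data = training.matrix.data.loc[common]
    test_data = test.data.loc[common]
    if standardize:
        train_data = _zscore_rows(train_data)
        test_data = _zscore_rows(test_data)
    train_mx = ExpressionMatrix(train_data, training.matrix.annotations)
    test_mx = ExpressionMatrix(test_data, test.annotations)

    model = fit_metagene_model(
        train_mx, training.labels, k=k_eff, m=min(m, train_mx.n_samples - 1),
        mode=mode, seed=seed,
    )
    probs = predict_matrix(model, test_mx)
    groups = (
        test.groups().to_numpy()
        if test.annotations is not None
        else np.array(["all"] * test.n_samples)
    )
    table = pd.DataFrame(
        {"sample_id": test.sample_ids, "group": groups, "probability": probs}
    )
    return PathwayActivity(pathway=training.name, table=table, model=model)


def one_way_anova_bonferroni(values, groups) -> GroupComparison:
    """One-way ANOVA plus Bonferroni-adjusted pairwise t tests.

    Pairwise t statistics use the pooled within-group mean square with
    N - g degrees of freedom; adjusted p = min(1, raw p x number of
    pairs).  Every group needs at least 2 observations.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    names = list(pd.unique(g))
    if len(names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    by = {name: v[g == name] for name in names}
    for name, arr in by.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    n_total = v.size
    grand = v.mean()
    ss_between = sum(arr.size * (arr.mean() - grand) ** 2 for arr in by.values())
    ss_within = sum(((arr - arr.mean()) ** 2).sum() for arr in by.values())
    df_b = len(names) - 1
    df_w = n_total - len(names)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f_stat = 0.0 if ms_b == 0 else np.inf
        p = 1.0 if ms_b == 0 else np.nextafter(0, 1)
    else:
        f_stat = ms_b / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = []
    for a, b in itertools.combinations(names, 2):
        xa, xb = by[a], by[b]
        if ms_w == 0:
            t = 0.0 if xa.mean() == xb.mean() else np.inf * np.sign(xa.mean() - xb.mean())
            p_raw = 1.0 if xa.mean() == xb.mean() else 0.0
        else:
            se = np.sqrt(ms_w * (1 / xa.size + 1 / xb.size))
            t = float((xa.mean() - xb.mean()) / se)
            p_raw = float(2 * stats.t.sf(abs(t), df_w))
        pairwise.append(
            {
                "group_a": str(a),
                "group_b": str(b),
                "t": t,
                "p_raw": p_raw,
                "p_adjusted": min(1.0, p_raw * n_pairs),
            }
        )
    return GroupComparison(
        f_statistic=float(f_stat),
        p_value=float(min(max(p, 0.0), 1.0)),
        df_between=df_b,
        df_within=df_w,
        pairwise=pairwise,
    )
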