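"""Supervised metagene probit classification.

The signature-building procedure: (1) rank every probe by the absolute
Pearson correlation between its expression and the binary exposure label
and keep the top k ("the signature"); (2) center each selected probe by
its training mean and take the thin singular value decomposition of the
k x n selected submatrix, X = U D V^T; the top m right singular vectors
("metagenes") give each training sample an m-dimensional score; (3) fit a
probit regression P(y = 1) = Phi(b0 + b^T v) on the scores.

Two fitting modes: "map" — deterministic Newton maximization of the
ridge-penalized log-likelihood (penalty lambda * ||b||^2, intercept
unpenalized; the ridge keeps the perfectly separable case finite); and
"bayes" — Albert–Chib latent-variable Gibbs sampling with independent
N(0, 100) priors, reported as the posterior mean of Phi.

A new sample x* is scored by centering with the stored training means,
projecting v* = x*^T U_m D_m^{-1}, and evaluating the fitted probit.
Leave-one-out cross-validation repeats the whole procedure — probe
selection included — inside every fold.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .formats import ExpressionMatrix

__all__ = [
    "Signature",
    "MetageneModel",
    "PredictionSet",
    "RocSummary",
    "ConvergenceError",
    "select_probes",
    "fit_metagene_model",
    "predict_probability",
    "predict_matrix",
    "loocv",
    "roc_summary",
    "cross_predict",
]

_PHI_EPS = 1e-12


class ConvergenceError(RuntimeError):
    """Newton iteration failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclasses.dataclass
class Signature:
    """Ordered probe list: strongest |correlation| first.

    ``entries`` has columns probe_id, statistic (the selection Pearson r
    against the 0/1 label) and direction ('up' if r > 0 — higher in the
    exposed class — else 'down').
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "statistic", "direction"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"signature entries need columns {sorted(required)}")
        if self.entries["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids in signature")
        stat = self.entries["statistic"].abs().to_numpy()
        if np.any(np.diff(stat) > 1e-12):
            raise ValueError("signature entries must be sorted by |statistic| descending")

    @property
    def k(self) -> int:
        return len(self.entries)

    @property
    def probe_ids(self) -> list[str]:
        return self.entries["probe_id"].tolist()

    def up_probes(self) -> list[str]:
        return self.entries.loc[self.entries["direction"] == "up", "probe_id"].tolist()

    def down_probes(self) -> list[str]:
        return self.entries.loc[self.entries["direction"] == "down", "probe_id"].tolist()

    def save_tsv(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path: str | Path) -> "Signature":
        return cls(pd.read_csv(path, sep="\t", dtype={"probe_id": str}))


@dataclasses.dataclass
class MetageneModel:
    """Everything needed to score a new sample."""

    signature: Signature
    probe_means: pd.Series           # training mean per signature probe
    components: np.ndarray           # U_m, k x m left singular vectors
    singular_values: np.ndarray      # D_m, length m, strictly positive
    coefficients: np.ndarray         # [b0, b_1..b_m]
    fit_mode: str                    # "map" or "bayes"
    diagnostics: dict = dataclasses.field(default_factory=dict)
    coefficient_draws: np.ndarray | None = None  # bayes posterior draws

    @property
    def m(self) -> int:
        return int(self.singular_values.shape[0])

    def project(self, matrix: ExpressionMatrix) -> np.ndarray:
        """Metagene scores for each sample (n x m): v* = x*^T U_m D_m^{-1}."""
        probes = self.signature.probe_ids
        missing = [p for p in probes if p not in matrix.data.index]
        if missing:
            raise KeyError(
                f"{len(missing)} signature probes missing from matrix: {missing[:5]}"
            )
        X = matrix.data.loc[probes].to_numpy()
        Xc = X - self.probe_means.to_numpy()[:, None]
        return Xc.T @ self.components / self.singular_values

    def to_json(self, path: str | Path) -> None:
        doc = {
            "signature": self.signature.entries.to_dict(orient="list"),
            "probe_means": self.probe_means.tolist(),
            "components": self.components.tolist(),
            "singular_values": self.singular_values.tolist(),
            "coefficients": self.coefficients.tolist(),
            "fit_mode": self.fit_mode,
            "diagnostics": self.diagnostics,
        }
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "MetageneModel":
        doc = json.loads(Path(path).read_text())
        sig = Signature(pd.DataFrame(doc["signature"]))
        return cls(
            signature=sig,
            probe_means=pd.Series(doc["probe_means"], index=sig.probe_ids),
            components=np.asarray(doc["components"], dtype=float),
            singular_values=np.asarray(doc["singular_values"], dtype=float),
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            fit_mode=doc["fit_mode"],
            diagnostics=doc.get("diagnostics", {}),
        )


@dataclasses.dataclass
class PredictionSet:
    """Per-sample predicted probability with its true class and fold."""

    table: pd.DataFrame  # sample_id, true_class, probability, fold

    def __post_init__(self) -> None:
        p = self.table["probability"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")

    def save_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclasses.dataclass
class RocSummary:
    auc: float
    sensitivity: float
    specificity: float
    auc_se: float
    p_value: float
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def _check_labels(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels, dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise ValueError("labels must be coded 0 (control) / 1 (exposed)")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return y


def labels_from_groups(matrix: ExpressionMatrix, exposed_group: str) -> np.ndarray:
    """0/1 label vector: 1 where the sample's group equals exposed_group."""
    return (matrix.groups() == exposed_group).to_numpy().astype(float)


# ---------------------------------------------------------------------------
# probe selection
# ---------------------------------------------------------------------------

def select_probes(matrix: ExpressionMatrix, labels, k: int) -> Signature:
    """Top-k probes by |Pearson correlation| with the 0/1 exposure label.

    Constant probes get statistic 0; ties in |r| are broken by probe id
    ascending so selection is fully deterministic.
    """
    y = _check_labels(labels)
    if k > matrix.n_probes:
        raise ValueError(f"k={k} exceeds probe count {matrix.n_probes}")
    X = matrix.values
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ yc) / (sx * sy)
    r[sx == 0] = 0.0
    frame = pd.DataFrame({"probe_id": matrix.probe_ids, "statistic": r})
    frame["abs_r"] = frame["statistic"].abs()
    frame = frame.sort_values(
        ["abs_r", "probe_id"], ascending=[False, True], kind="mergesort"
    ).head(k)
    frame["direction"] = np.where(frame["statistic"] > 0, "up", "down")
    return Signature(frame.drop(columns="abs_r").reset_index(drop=True))


# ---------------------------------------------------------------------------
# probit fitting
# ---------------------------------------------------------------------------

def _probit_loglik_terms(eta: np.ndarray, y: np.ndarray):
    Phi = np.clip(stats.norm.cdf(eta), _PHI_EPS, 1 - _PHI_EPS)
    phi = stats.norm.pdf(eta)
    ll = np.sum(y * np.log(Phi) + (1 - y) * np.log(1 - Phi))
    grad_eta = y * phi / Phi - (1 - y) * phi / (1 - Phi)
    hess_eta = -y * phi * (eta * Phi + phi) / Phi**2 - (1 - y) * phi * (
        phi - eta * (1 - Phi)
    ) / (1 - Phi) ** 2
    return ll, grad_eta, hess_eta


def _fit_probit_map(
    Z: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, dict]:
    """Newton maximization of the ridge-penalized probit log-likelihood.

    Z is the design matrix including the leading intercept column; the
    penalty lambda * ||b||^2 excludes the intercept.  Converges when the
    parameter step's max-norm falls below tol.
    """
    p = Z.shape[1]
    beta = np.zeros(p)
    pen_mask = np.ones(p)
    pen_mask[0] = 0.0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        ll, g_eta, h_eta = _probit_loglik_terms(eta, y)
        obj = ll - ridge * np.sum(pen_mask * beta**2)
        trace.append(float(obj))
        grad = Z.T @ g_eta - 2.0 * ridge * pen_mask * beta
        hess = (Z * h_eta[:, None]).T @ Z - 2.0 * ridge * np.diag(pen_mask)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {it}", trace) from exc
        beta = beta - step
        if np.max(np.abs(step)) < tol:
            return beta, {"iterations": it, "objective": float(obj), "converged": True}
    raise ConvergenceError(
        f"probit Newton did not converge in {max_iter} iterations", trace
    )


def _fit_probit_bayes(
    Z: np.ndarray,
    y: np.ndarray,
    seed: int,
    n_draws: int = 2000,
    n_burn: int = 500,
    prior_var: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Albert–Chib Gibbs sampler for the probit model.

    Latent z_i ~ N(eta_i, 1) truncated to the observed side; coefficients
    have independent N(0, prior_var) priors.  Returns the posterior-mean
    coefficient vector plus all retained draws.
    """
    rng = np.random.default_rng(seed)
    n, p = Z.shape
    prec = Z.T @ Z + np.eye(p) / prior_var
    cov = np.linalg.inv(prec)
    chol = np.linalg.cholesky(cov)
    beta = np.zeros(p)
    draws = np.empty((n_draws, p))
    pos = y == 1
    for t in range(n_burn + n_draws):
        eta = Z @ beta
        u = rng.uniform(size=n)
        # inverse-CDF truncated normal draw on each observation's side
        lo = stats.norm.cdf(-eta)
        z = np.empty(n)
        z[pos] = eta[pos] + stats.norm.ppf(lo[pos] + u[pos] * (1 - lo[pos]))
        z[~pos] = eta[~pos] + stats.norm.ppf(u[~pos] * lo[~pos])
        z = np.clip(z, -38, 38)
        mean = cov @ (Z.T @ z)
        beta = mean + chol @ rng.standard_normal(p)
        if t >= n_burn:
            draws[t - n_burn] = beta
    post_mean = draws.mean(axis=0)
    return post_mean, draws, {"n_draws": n_draws, "n_burn": n_burn}


def fit_metagene_model(
    matrix: ExpressionMatrix,
    labels,
    k: int = 250,
    m: int = 2,
    mode: str = "map",
    seed: int = 0,
    ridge: float = 0.5,
) -> MetageneModel:
    """Select probes, extract metagenes, and fit the probit classifier."""
    y = _check_labels(labels)
    n = matrix.n_samples
    if m > n - 1:
        raise ValueError(f"m={m} exceeds training samples - 1 = {n - 1}")
    if m < 1:
        raise ValueError("m must be >= 1")
    sig = select_probes(matrix, y, k)
    X = matrix.data.loc[sig.probe_ids].to_numpy()
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    U, d, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = d > max(d.max(), 1.0) * 1e-12
    U, d, Vt = U[:, keep], d[keep], Vt[keep]
    if d.shape[0] < m:
        raise ValueError(f"rank {d.shape[0]} of centered submatrix is below m={m}")
    U_m, d_m, V_m = U[:, :m], d[:m], Vt[:m].T
    Z = np.column_stack([np.ones(n), V_m])
    if mode == "map":
        coef, diag = _fit_probit_map(Z, y, ridge=ridge)
        draws = None
    elif mode == "bayes":
        coef, draws, diag = _fit_probit_bayes(Z, y, seed=seed)
    else:
        raise ValueError(f"unknown fit mode {mode!r}")
    return MetageneModel(
        signature=sig,
        probe_means=pd.Series(means, index=sig.probe_ids),
        components=U_m,
        singular_values=d_m,
        coefficients=coef,
        fit_mode=mode,
        diagnostics=diag,
        coefficient_draws=draws,
    )


def _scores_to_probability(model: MetageneModel, V: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones(V.shape[0]), V])
    if model.fit_mode == "bayes" and model.coefficient_draws is not None:
        # posterior mean of Phi over retained draws
        return stats.norm.cdf(Z @ model.coefficient_draws.T).mean(axis=1)
    return stats.norm.cdf(Z @ model.coefficients)


def predict_matrix(model: MetageneModel, matrix: ExpressionMatrix) -> np.ndarray:
    """Predicted exposure probability for every sample of a matrix."""
    return _scores_to_probability(model, model.project(matrix))


def predict_probability(model: MetageneModel, sample: pd.Series) -> float:
    """Score one sample given as a probe_id -> value Series."""
    missing = [p for p in model.signature.probe_ids if p not in sample.index]
    if missing:
        raise KeyError(f"sample lacks signature probes: {missing[:5]}")
    x = sample.loc[model.signature.probe_ids].to_numpy(dtype=float)
    v = (x - model.probe_means.to_numpy()) @ model.components / model.singular_values
    return float(_scores_to_probability(model, v[None, :])[0])


# ---------------------------------------------------------------------------
# cross-validation and ROC
# ---------------------------------------------------------------------------

def loocv(
    matrix: ExpressionMatrix,
    labels,
    k: int = 250,
    m: int = 2,
    mode: str = "map",
    seed: int = 0,
    ridge: float = 0.5,
    fixed_signature: bool = False,
) -> PredictionSet:
    """Leave-one-out cross-validation with per-fold probe selection.

    Each sample is scored by a model trained on the other n - 1; probe
    selection is repeated inside the fold (honest CV).  With
    ``fixed_signature`` the signature is chosen once on the full data and
    only the SVD/probit refit per fold (the optimistic variant).  Folds
    whose training labels collapse to one class yield a NaN probability
    and fold id 'unpredictable'.
    """
    y = _check_labels(labels)
    n = matrix.n_samples
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    fixed_probes = select_probes(matrix, y, k).probe_ids if fixed_signature else None
    rows = []
    for i, sample_id in enumerate(matrix.sample_ids):
        keep = [j for j in range(n) if j != i]
        y_tr = y[keep]
        if np.unique(y_tr).size < 2:
            rows.append((sample_id, int(y[i]), np.nan, "unpredictable"))
            continue
        cols = [matrix.sample_ids[j] for j in keep]
        ann = None if matrix.annotations is None else matrix.annotations.loc[cols]
        train = ExpressionMatrix(matrix.data[cols], ann)
        if fixed_probes is not None:
            train = ExpressionMatrix(train.data.loc[fixed_probes], ann)
            k_fold = len(fixed_probes)
        else:
            k_fold = k
        model = fit_metagene_model(
            train, y_tr, k=k_fold, m=min(m, len(cols) - 1), mode=mode,
            seed=seed + i, ridge=ridge,
        )
        prob = predict_probability(model, matrix.data[sample_id])
        rows.append((sample_id, int(y[i]), prob, f"fold_{i:02d}"))
    table = pd.DataFrame(rows, columns=["sample_id", "true_class", "probability", "fold"])
    return PredictionSet(table)


def roc_summary(predictions: PredictionSet, threshold: float = 0.5) -> RocSummary:
    """AUC (Mann–Whitney, ties count 1/2), sensitivity/specificity at the
    threshold, Hanley–McNeil standard error, and a two-sided normal test
    of AUC = 0.5."""
    tab = predictions.table.dropna(subset=["probability"])
    pos = tab.loc[tab["true_class"] == 1, "probability"].to_numpy()
    neg = tab.loc[tab["true_class"] == 0, "probability"].to_numpy()
    if pos.size == 0 or neg.size == 0:
        raise ValueError("ROC needs predictions from both classes")
    diff = pos[:, None] - neg[None, :]
    auc = float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))
    sens = float(np.mean(pos > threshold))
    spec = float(np.mean(neg <= threshold))
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (pos.size - 1) * (q1 - auc**2)
        + (neg.size - 1) * (q2 - auc**2)
    ) / (pos.size * neg.size)
    se = float(np.sqrt(max(var, 0.0)))
    if se > 0:
        z = (auc - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return RocSummary(auc=auc, sensitivity=sens, specificity=spec, auc_se=se,
                      p_value=p, threshold=threshold)


def cross_predict(
    model: MetageneModel,
    other_matrix: ExpressionMatrix,
    other_labels,
    threshold: float = 0.5,
) -> tuple[PredictionSet, RocSummary]:
    """Score another cohort with a frozen model (dose-specificity test)."""
    y = _check_labels(other_labels)
    probs = predict_matrix(model, other_matrix)
    table = pd.DataFrame(
        {
            "sample_id": other_matrix.sample_ids,
            "true_class": y.astype(int),
            "probability": probs,
            "fold": "external",
        }
    )
    preds = PredictionSet(table)
    return preds, roc_summary(preds, threshold)
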