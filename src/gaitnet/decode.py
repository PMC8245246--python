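"""SVM decoding of the two imagery classes and repeated-measures statistics.

Classification is stratified k-fold with all fitted transforms —
standardization and, when per-trial connectivity matrices are supplied, the
adjacency spatial filter — fitted inside each training fold, so no test
information leaks into the features. Accuracies are reported as
mean% +- std% across folds.

The statistics mirror the study's design: characteristic path lengths of a
15-channel subset, compared pairwise across tasks by one-way
repeated-measures ANOVA on paired trials, at alpha = 0.05. The grid pairs
every channel of one task with every channel of the other, an unusual
cross-channel design reproduced deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import AdjacencySpatialFilter, FeatureTable

#: 15-channel subset used for the path-length statistics.
STATS_CHANNELS = ["F3", "F4", "FC3", "FC4", "C3", "Cz", "C4", "CP3", "CP4",
                  "P3", "Pz", "P4", "O1", "O2", "Oz"]


@dataclass
class ClassifierReport:
    """Cross-validated accuracy of one feature family."""

    family: str
    fold_accuracies: np.ndarray  # percent
    confusion: np.ndarray  # (2, 2) counts, rows = true
    classes: list[str]
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1))

    def summary(self) -> str:
        return (
            f"{self.family}: {self.mean_accuracy:.2f}% +- "
            f"{self.std_accuracy:.2f}% "
            f"({len(self.fold_accuracies)}-fold CV, classes {self.classes})"
        )


def train_eval_svm(features: FeatureTable, cv_folds: int = 5,
                   kernel: str = "rbf", C: float = 1.0, gamma="scale",
                   seed: int = 0,
                   adj_weights: np.ndarray | None = None,
                   n_csp: int = 16) -> ClassifierReport:
    """Stratified k-fold SVM evaluation.

    If ``adj_weights`` (per-trial N x N connectivity weight matrices) is
    given, the adjacency spatial filter is fitted on each training fold and
    its features appended to ``features.matrix`` — the combination family.
    """
    y = np.asarray(features.labels)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < cv_folds:
        raise ValueError(f"need >= {cv_folds} trials per class, got {counts}")
    x = features.matrix
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    accs, conf = [], np.zeros((len(classes), len(classes)), dtype=int)
    for train_idx, test_idx in skf.split(x, y):
        x_tr, x_te = x[train_idx], x[test_idx]
        if adj_weights is not None:
            csp = AdjacencySpatialFilter(n_components=n_csp)
            csp.fit(adj_weights[train_idx], y[train_idx])
            x_tr = np.hstack([x_tr, csp.transform(adj_weights[train_idx])])
            x_te = np.hstack([x_te, csp.transform(adj_weights[test_idx])])
        scaler = StandardScaler().fit(x_tr)
        clf = SVC(kernel=kernel, C=C, gamma=gamma)
        clf.fit(scaler.transform(x_tr), y[train_idx])
        pred = clf.predict(scaler.transform(x_te))
        accs.append(100.0 * np.mean(pred == y[test_idx]))
        conf += confusion_matrix(y[test_idx], pred, labels=classes)
    family = features.family + ("+adjspace" if adj_weights is not None else "")
    return ClassifierReport(
        family, np.asarray(accs), conf, classes,
        {"kernel": kernel, "C": C, "gamma": gamma, "cv_folds": cv_folds,
         "seed": seed, "n_csp": n_csp if adj_weights is not None else None},
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def rm_anova_1way(data: np.ndarray) -> tuple[float, float]:
    """One-way repeated-measures ANOVA on (n_subjects, k_conditions) data.

    Returns (F, p) with df = (k-1, (k-1)(n-1)). Subject (row) is the
    repeated factor.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    grand = data.mean()
    ss_cond = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_err = ss_err / df2
    if ms_err <= 0:
        return 0.0, 1.0
    f = (ss_cond / df1) / ms_err
    return float(f), float(stats.f.sf(f, df1, df2))


@dataclass
class AnovaTable:
    """Channel x channel p-value grid for one task pair."""

    p_values: np.ndarray
    f_values: np.ndarray
    channels_row: list[str]
    channels_col: list[str]
    task_pair: tuple[str, str]
    alpha: float = 0.05

    @property
    def significant(self) -> np.ndarray:
        return self.p_values < self.alpha

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p_values, index=self.channels_row,
                            columns=self.channels_col)


def rm_anova_path_length(nodal_pl: dict[str, np.ndarray],
                         channel_names: list[str],
                         task_pair: tuple[str, str],
                         channels: list[str] | None = None,
                         alpha: float = 0.05) -> AnovaTable:
    """Pairwise task comparison of nodal path lengths on a channel grid.

    ``nodal_pl`` maps task label -> (n_trials, n_channels) nodal path
    lengths; trials must be matched (paired) across the two tasks. Cell
    (a, b) compares channel a under ``task_pair[0]`` with channel b under
    ``task_pair[1]`` by one-way repeated-measures ANOVA across the paired
    trials — including the cross-channel cells.
    """
    t1, t2 = task_pair
    x1, x2 = np.asarray(nodal_pl[t1]), np.asarray(nodal_pl[t2])
    if x1.shape[0] != x2.shape[0]:
        raise ValueError(
            f"unpaired design: {x1.shape[0]} vs {x2.shape[0]} trials; "
            "repeated measures needs matched trials"
        )
    n = x1.shape[0]
    if n < 2:
        raise ValueError("need >= 2 paired trials")
    channels = channels or [c for c in STATS_CHANNELS if c in channel_names]
    idx = []
    for c in channels:
        if c not in channel_names:
            raise ValueError(f"channel {c!r} not in data")
        idx.append(channel_names.index(c))
    a1, a2 = x1[:, idx], x2[:, idx]  # (n, m)
    # vectorized paired two-condition RM ANOVA: F = t_paired^2, df (1, n-1)
    d = a1[:, :, None] - a2[:, None, :]  # (n, m, m)
    mean_d = d.mean(axis=0)
    var_d = d.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(var_d > 0, n * mean_d**2 / var_d, 0.0)
    p = stats.f.sf(f, 1, n - 1)
    p = np.where(var_d > 0, p, 1.0)
    return AnovaTable(p, f, list(channels), list(channels), task_pair, alpha)


def rm_anova_all_pairs(nodal_pl: dict[str, np.ndarray],
                       channel_names: list[str],
                       channels: list[str] | None = None,
                       alpha: float = 0.05) -> dict[tuple[str, str], AnovaTable]:
    """The three pairwise task comparisons (MCI-REST, IEG-REST, MCI-IEG)."""
    tasks = list(nodal_pl)
    out = {}
    for i in range(len(tasks)):
        for j in range(i + 1, len(tasks)):
            pair = (tasks[i], tasks[j])
            out[pair] = rm_anova_path_length(nodal_pl, channel_names, pair,
                                             channels, alpha)
    return out


def holm_correct(table: AnovaTable) -> AnovaTable:
    """Holm step-down corrected copy of an AnovaTable (optional; the study
    reports raw p-values)."""
    p = table.p_values.ravel()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty_like(p)
    running = 0.0
    for rank, k in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[k]))
        adj[k] = running
    return AnovaTable(adj.reshape(table.p_values.shape), table.f_values,
                      table.channels_row, table.channels_col,
                      table.task_pair, table.alpha)
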