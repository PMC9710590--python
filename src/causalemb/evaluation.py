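"""Cross-validation of signed gene–function prediction.

Protocol: a balanced test set is drawn from the association matrix Y — n
entries with value +1, n with value -1 and 2n zero entries — restricted to
leaf functions of the hierarchy supported by at least ``min_genes`` genes
(parents inherit from descendants, so masking a parent would leak through
its children). The drawn entries are set to zero, the per-function
regression is refit on the masked matrix (gene embeddings depend only on
the expression graph, so they are not retrained), and the refit scores of
the held-out entries are evaluated on two tasks:

* absolute prediction — does a causal relation exist at all? |s| against
  the 4n entries, label "entry was nonzero";
* sign prediction — activation or inhibition? signed s against the 2n
  nonzero entries, label "entry was +1". The ROC of the opposite subcase
  (inhibition vs activation) is the same curve flipped:
  TPR -> 1 - TPR, FPR -> 1 - FPR.

Metrics: trapezoidal AUC and precision in the low-recall limit (default
5%), the latter measuring how precise the very top-scoring predictions are.
Replicates are aggregated as mean +- SD; curves are averaged vertically on
a fixed 101-point grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from .embed_spectral import EmbeddingMatrix
from .function_space import fit_function_embeddings, score_genes
from .knowledge_model import AssociationMatrix, Ontology

logger = logging.getLogger(__name__)

DEFAULT_N = 1000
DEFAULT_K_REPLICATES = 50
DEFAULT_MIN_GENES = 10
DEFAULT_RECALL_LIMIT = 0.05
CURVE_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class TestSet:
    """One balanced cross-validation draw: masked (gene, function, value)."""

    entries: list[tuple[str, str, int]]
    replicate: int

    @property
    def composition(self) -> tuple[int, int, int]:
        vals = [v for _, _, v in self.entries]
        return (sum(v == 1 for v in vals), sum(v == -1 for v in vals),
                sum(v == 0 for v in vals))


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray

    def flipped(self) -> "ROCCurve":
        """The ROC of the opposite sign subcase (inhibition vs activation,
        scored with -s): true and false positive rates trade places and
        complement, i.e. the curve is reflected through the anti-diagonal."""
        return ROCCurve(fpr=(1.0 - self.tpr)[::-1], tpr=(1.0 - self.fpr)[::-1])


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray


@dataclass
class ReplicateResult:
    scores_abs: np.ndarray
    labels_abs: np.ndarray
    scores_sign: np.ndarray
    labels_sign: np.ndarray


@dataclass
class CVReport:
    replicates: list[ReplicateResult] = field(default_factory=list)

    def metric_arrays(self, recall_limit: float = DEFAULT_RECALL_LIMIT
                      ) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {
            "auc_abs": [], "prec_abs": [], "auc_sign": [], "prec_sign": [],
        }
        for r in self.replicates:
            roc_a, prc_a = roc_prc(r.scores_abs, r.labels_abs)
            roc_s, prc_s = roc_prc(r.scores_sign, r.labels_sign)
            out["auc_abs"].append(auc(roc_a))
            out["prec_abs"].append(precision_at_recall(prc_a, recall_limit))
            out["auc_sign"].append(auc(roc_s))
            out["prec_sign"].append(precision_at_recall(prc_s, recall_limit))
        return {k: np.asarray(v) for k, v in out.items()}

    def summary(self, recall_limit: float = DEFAULT_RECALL_LIMIT
                ) -> dict[str, dict[str, float]]:
        arrays = self.metric_arrays(recall_limit)
        return aggregate_replicates(arrays)


def make_test_sets(
    Y: AssociationMatrix,
    ont: Ontology,
    n: int = DEFAULT_N,
    k: int = DEFAULT_K_REPLICATES,
    min_genes: int = DEFAULT_MIN_GENES,
    seed: int = 0,
) -> list[TestSet]:
    """Draw k independent balanced test sets from Y.

    Eligible functions are hierarchy leaves supported by at least
    ``min_genes`` genes. Zero entries are sampled uniformly over the
    (gene, eligible function) cells with Y = 0.
    """
    leaves = set(ont.leaves(Y.functions))
    dense = np.asarray(Y.matrix.todense())
    support = (dense != 0).sum(axis=0)
    eligible = [j for j, f in enumerate(Y.functions)
                if f in leaves and support[j] >= min_genes]
    if not eligible:
        raise ValueError(
            f"no eligible functions (leaves with >= {min_genes} genes)")
    sub = dense[:, eligible]
    pos = np.argwhere(sub == 1)
    neg = np.argwhere(sub == -1)
    zero = np.argwhere(sub == 0)
    for name, pool, need in (("+1", pos, n), ("-1", neg, n),
                             ("0", zero, 2 * n)):
        if len(pool) < need:
            raise ValueError(
                f"eligible pool of {name} entries has {len(pool)} cells; "
                f"need at least {need}")

    seeds = np.random.SeedSequence(seed).spawn(k)
    sets = []
    for rep, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        chosen = []
        for pool, need, val in ((pos, n, 1), (neg, n, -1), (zero, 2 * n, 0)):
            idx = rng.choice(len(pool), size=need, replace=False)
            for i, jj in pool[idx]:
                chosen.append((Y.genes[i], Y.functions[eligible[jj]], val))
        sets.append(TestSet(entries=chosen, replicate=rep))
    return sets


def run_cross_validation(
    U: EmbeddingMatrix,
    Y: AssociationMatrix,
    test_sets: list[TestSet],
) -> CVReport:
    """Mask each test set, refit the per-function regression, score the
    held-out entries. Y is restored after every replicate (asserted)."""
    original = Y.matrix.copy()
    report = CVReport()
    for ts in test_sets:
        masked = np.asarray(Y.matrix.todense())
        gi = [Y.gene_index(g) for g, _, _ in ts.entries]
        fj = [Y.function_index(f) for _, f, _ in ts.entries]
        masked[gi, fj] = 0
        from scipy import sparse as _sp
        Ymasked = AssociationMatrix(list(Y.genes), list(Y.functions),
                                    _sp.csr_matrix(masked), dict(Y.terms))
        F = fit_function_embeddings(U, Ymasked)
        S = score_genes(U, F).scores
        s = S[gi, fj]
        truth = np.array([v for _, _, v in ts.entries])

        nz = truth != 0
        report.replicates.append(ReplicateResult(
            scores_abs=np.abs(s),
            labels_abs=nz.astype(int),
            scores_sign=s[nz],
            labels_sign=(truth[nz] > 0).astype(int),
        ))
    assert (Y.matrix != original).nnz == 0, "Y was mutated by cross-validation"
    return report


def roc_prc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[ROCCurve, PRCurve]:
    """ROC and precision–recall curves; equal scores cross every threshold
    together (threshold grouping)."""
    fpr, tpr, _ = skmetrics.roc_curve(labels, scores)
    precision, recall, _ = skmetrics.precision_recall_curve(labels, scores)
    return ROCCurve(fpr, tpr), PRCurve(recall[::-1], precision[::-1])


def auc(curve: ROCCurve | PRCurve) -> float:
    """Trapezoidal area under the curve."""
    if isinstance(curve, ROCCurve):
        x, y = curve.fpr, curve.tpr
    else:
        x, y = curve.recall, curve.precision
    order = np.argsort(x, kind="stable")
    return float(np.trapezoid(y[order], x[order]))


def precision_at_recall(curve: PRCurve, r: float = DEFAULT_RECALL_LIMIT
                        ) -> float:
    """Precision at the smallest achieved recall >= r (low-recall limit).

    If several thresholds achieve that recall, the strictest one (highest
    precision) is reported — it predicts the same true positives with the
    fewest false positives.
    """
    achieved = curve.recall[curve.recall >= r]
    if achieved.size == 0:
        return float("nan")
    r_star = achieved.min()
    at = np.isclose(curve.recall, r_star)
    return float(curve.precision[at].max())


def average_curves_roc(curves: list[ROCCurve],
                       grid: np.ndarray = CURVE_GRID
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical averaging of ROC curves on a fixed FPR grid."""
    ys = np.vstack([np.interp(grid, c.fpr, c.tpr) for c in curves])
    return grid, ys.mean(axis=0), ys.std(axis=0)


def average_curves_prc(curves: list[PRCurve],
                       grid: np.ndarray = CURVE_GRID
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical averaging of PR curves on a fixed recall grid."""
    ys = []
    for c in curves:
        order = np.argsort(c.recall, kind="stable")
        ys.append(np.interp(grid, c.recall[order], c.precision[order]))
    ys = np.vstack(ys)
    return grid, ys.mean(axis=0), ys.std(axis=0)


def aggregate_replicates(arrays: dict[str, np.ndarray]
                         ) -> dict[str, dict[str, float]]:
    """Mean and SD across replicates for each named metric."""
    return {
        name: {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
        for name, vals in arrays.items()
    }
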