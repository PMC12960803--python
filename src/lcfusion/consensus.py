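"""Ensemble fusion of harmonized land-cover maps into a consensus map.

Three fusion rules are provided, all operating per pixel on the class codes
``a_d`` assigned by the D input maps:

* **Weighted voting (WV)** — each map votes for its own class with a weight
  equal to its per-class F1 score estimated on the validation sample:
  ``score(c) = sum_{d: a_d = c} F1[d, c]``; the consensus class maximises
  the score.
* **Accuracy–confusion scoring (AccCo)** — each candidate class is credited
  with the correct-classification probabilities of the maps that voted for
  it and debited with misclassification probabilities contributed by the
  maps that voted otherwise, using each map's row-normalised conditional
  confusion ``q_d(reference = c | mapped = a)``:
  ``score(c) = sum_{d: a_d = c} q_d(c|c) - sum_{d: a_d != c} q_d(c|a_d)``.
  Scores may be negative; the argmax is taken over raw scores.  A
  ``variant="column"`` switch draws the penalty term from the
  column-normalised matrix instead (the conditioning direction of the
  published description is ambiguous; row-normalised is the default).
* **Random-forest stacking (RF)** — each map's vote is encoded as a sparse
  D*C feature vector holding the map's F1 score at the voted class and zero
  elsewhere, and a 500-tree random forest trained on labeled points predicts
  the consensus class.

Ties in WV/AccCo are broken first by the larger number of supporting maps,
then by the lowest class code — deterministic and independent of input
ordering.  Pixels where every map is nodata stay nodata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .accuracy import accuracy_report, cross_tabulate
from .raster import CategoricalRaster, assert_aligned
from .sampling import ValidationSample

__all__ = [
    "ConsensusModel",
    "fit_weights",
    "consensus_wv",
    "consensus_accco",
    "encode_rf_features",
    "consensus_rf",
]


@dataclass
class ConsensusModel:
    """Per-dataset, per-class fusion weights plus the rule identifier.

    ``f1_weights`` is a D x C array of per-class F1 scores (0 for classes a
    dataset never maps); ``cond_conf[d]`` is that dataset's C x C
    row-normalised conditional confusion (rows = mapped class, columns =
    reference class).  ``empty_rows[d]`` flags mapped classes with no sample
    support, whose conditional rows are zero.
    """

    classes: tuple
    dataset_names: tuple
    f1_weights: np.ndarray
    cond_conf: list
    cond_conf_col: list = field(default_factory=list)
    empty_rows: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.classes = tuple(int(c) for c in self.classes)
        self.f1_weights = np.asarray(self.f1_weights, dtype=float)
        d, c = self.f1_weights.shape
        if len(self.dataset_names) != d or len(self.classes) != c:
            raise ValueError("f1_weights shape inconsistent with datasets/classes")
        if ((self.f1_weights < -1e-12) | (self.f1_weights > 1 + 1e-12)).any():
            raise ValueError("F1 weights must lie in [0, 1]")
        self.cond_conf = [np.asarray(m, dtype=float) for m in self.cond_conf]
        if self.empty_rows is None:
            self.empty_rows = np.zeros((d, c), dtype=bool)
        for di, m in enumerate(self.cond_conf):
            rows = m.sum(axis=1)
            ok = np.isclose(rows, 1.0, atol=1e-9) | self.empty_rows[di]
            if not ok.all():
                raise ValueError(f"dataset {di}: conditional confusion rows must sum to 1")

    @property
    def n_datasets(self) -> int:
        return self.f1_weights.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "classes": list(self.classes),
            "dataset_names": list(self.dataset_names),
            "f1_weights": self.f1_weights.tolist(),
            "cond_conf": [m.tolist() for m in self.cond_conf],
            "cond_conf_col": [m.tolist() for m in self.cond_conf_col],
            "empty_rows": self.empty_rows.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ConsensusModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            dataset_names=tuple(d["dataset_names"]),
            f1_weights=np.array(d["f1_weights"]),
            cond_conf=[np.array(m) for m in d["cond_conf"]],
            cond_conf_col=[np.array(m) for m in d["cond_conf_col"]],
            empty_rows=np.array(d["empty_rows"], dtype=bool),
        )


def _check_aligned(maps) -> None:
    rep = assert_aligned(maps)
    if not rep:
        raise ValueError(f"input maps not aligned: {rep.describe()}")


def fit_weights(
    maps,
    sample: ValidationSample,
    strata_weights: dict[int, float],
    classes=None,
    dataset_names=None,
) -> ConsensusModel:
    """Estimate fusion weights for every input map from one validation sample.

    For each map the per-class F1 scores and the row-normalised conditional
    confusion come from the stratified, area-weighted error matrix of
    :mod:`lcfusion.accuracy`.  Classes a dataset never maps get weight 0 and
    an empty-row flag.
    """
    maps = list(maps)
    _check_aligned(maps)
    if dataset_names is None:
        dataset_names = tuple(f"map_{i}" for i in range(len(maps)))
    if classes is None:
        domain = set()
        for m in maps:
            domain |= set(m.class_domain)
        domain |= set(sample.class_domain)
        classes = tuple(sorted(domain))
    classes = tuple(int(c) for c in classes)
    c = len(classes)

    f1 = np.zeros((len(maps), c))
    cond = []
    cond_col = []
    empty = np.zeros((len(maps), c), dtype=bool)
    for di, m in enumerate(maps):
        em = cross_tabulate(m, sample, strata_weights, classes=classes)
        rep = accuracy_report(em)
        f1[di] = [0.0 if np.isnan(rep.f1[k]) else rep.f1[k] for k in classes]
        p = em.proportions
        row_tot = p.sum(axis=1, keepdims=True)
        col_tot = p.sum(axis=0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(row_tot > 0, p / row_tot, 0.0)
            qc = np.where(col_tot > 0, p / col_tot, 0.0)
        empty[di] = (row_tot[:, 0] == 0)
        cond.append(q)
        cond_col.append(qc)
    return ConsensusModel(
        classes=classes,
        dataset_names=tuple(dataset_names),
        f1_weights=f1,
        cond_conf=cond,
        cond_conf_col=cond_col,
        empty_rows=empty,
    )


def _argmax_with_ties(scores: np.ndarray, support: np.ndarray, classes, any_vote: np.ndarray,
                      nodata: int) -> np.ndarray:
    """Lexicographic argmax over (score, support, -class code).

    ``scores`` and ``support`` have shape (C, n). Pixels with no votes at
    all become nodata.
    """
    best = np.full(scores.shape[1], nodata, dtype=np.int32)
    best_score = np.full(scores.shape[1], -np.inf)
    best_support = np.full(scores.shape[1], -1, dtype=np.int64)
    for k, code in enumerate(classes):  # ascending codes: earlier wins exact ties
        s = scores[k]
        sup = support[k]
        better = (s > best_score) | ((s == best_score) & (sup > best_support))
        best[better] = code
        best_score[better] = s[better]
        best_support[better] = sup[better]
    best[~any_vote] = nodata
    return best


def _vote_stack(maps):
    _check_aligned(maps)
    arr = np.stack([m.values for m in maps])  # (D, rows, cols)
    nod = np.array([m.nodata for m in maps]).reshape(-1, 1, 1)
    valid = arr != nod
    return arr, valid


def consensus_wv(maps, model: ConsensusModel) -> CategoricalRaster:
    """F1-weighted voting: per pixel the class with the highest sum of the
    voting maps' class F1 scores wins."""
    maps = list(maps)
    arr, valid = _vote_stack(maps)
    shape = arr.shape[1:]
    classes = model.classes
    scores = np.zeros((len(classes),) + shape)
    support = np.zeros((len(classes),) + shape, dtype=np.int64)
    for k, c in enumerate(classes):
        votes = (arr == c) & valid
        support[k] = votes.sum(axis=0)
        scores[k] = np.tensordot(model.f1_weights[:, k], votes, axes=(0, 0))
    any_vote = valid.any(axis=0)
    nodata = maps[0].nodata
    flat = _argmax_with_ties(
        scores.reshape(len(classes), -1),
        support.reshape(len(classes), -1),
        classes,
        any_vote.reshape(-1),
        nodata,
    )
    return CategoricalRaster(
        values=flat.reshape(shape),
        grid=maps[0].grid,
        nodata=nodata,
        class_domain=frozenset(classes) ,
    )


def consensus_accco(maps, model: ConsensusModel, variant: str = "row") -> CategoricalRaster:
    """Accuracy–confusion scoring: reward diagonal, penalise off-diagonal
    confusion probabilities; raw-score argmax with the standard tie rule."""
    if variant not in ("row", "column"):
        raise ValueError("variant must be 'row' or 'column'")
    maps = list(maps)
    arr, valid = _vote_stack(maps)
    shape = arr.shape[1:]
    classes = model.classes
    code_to_idx = {c: k for k, c in enumerate(classes)}
    penalty_mats = model.cond_conf if variant == "row" else model.cond_conf_col

    scores = np.zeros((len(classes),) + shape)
    support = np.zeros((len(classes),) + shape, dtype=np.int64)
    for d in range(len(maps)):
        q = model.cond_conf[d]
        qp = penalty_mats[d]
        vd = arr[d]
        val = valid[d]
        # index of the voted class per pixel (arbitrary where invalid)
        vidx = np.zeros(shape, dtype=np.int64)
        for c, k in code_to_idx.items():
            vidx[vd == c] = k
        for k, c in enumerate(classes):
            voted_c = (vd == c) & val
            other = val & ~voted_c
            support[k] += voted_c
            scores[k] += np.where(voted_c, q[k, k], 0.0)
            scores[k] -= np.where(other, qp[vidx, k], 0.0)
    any_vote = valid.any(axis=0)
    nodata = maps[0].nodata
    flat = _argmax_with_ties(
        scores.reshape(len(classes), -1),
        support.reshape(len(classes), -1),
        classes,
        any_vote.reshape(-1),
        nodata,
    )
    return CategoricalRaster(
        values=flat.reshape(shape),
        grid=maps[0].grid,
        nodata=nodata,
        class_domain=frozenset(classes),
    )


def encode_rf_features(maps, model: ConsensusModel, rows=None, cols=None) -> np.ndarray:
    """Sparse F1 encoding of the ensemble's votes.

    Feature (d, c) holds ``F1[d, c]`` when map d voted class c, else 0; a
    nodata vote leaves the whole block of map d zero.  Returns an (n, D*C)
    array over the requested cells (default: all cells, row-major).
    """
    maps = list(maps)
    _check_aligned(maps)
    classes = model.classes
    if rows is None:
        shape = maps[0].values.shape
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        rows, cols = rr.ravel(), cc.ravel()
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    n = rows.size
    ncls = len(classes)
    # code -> class index lookup table over the observed code range
    lut_size = max(max(classes), *(int(m.values.max(initial=0)) for m in maps)) + 1
    lut = np.full(lut_size, -1, dtype=np.int64)
    for k, c in enumerate(classes):
        lut[c] = k
    feats = np.zeros((n, len(maps) * ncls))
    for d, m in enumerate(maps):
        v = m.values[rows, cols]
        valid = v != m.nodata
        vidx = np.where((v >= 0) & (v < lut_size), lut[np.clip(v, 0, lut_size - 1)], -1)
        ok = valid & (vidx >= 0)
        feats[np.nonzero(ok)[0], d * ncls + vidx[ok]] = model.f1_weights[d, vidx[ok]]
    return feats


def consensus_rf(
    maps,
    model: ConsensusModel,
    training: ValidationSample,
    seed: int = 0,
    n_trees: int = 500,
    chunk: int = 200_000,
) -> CategoricalRaster:
    """Random-forest stacking over the F1-encoded ensemble votes.

    Trains a forest (``n_trees`` trees, library defaults otherwise, fixed
    seed) on the labeled training points and predicts every pixel where at
    least one map votes.  Raises when a training class has fewer than two
    points.
    """
    maps = list(maps)
    _check_aligned(maps)
    pts = training.resolved()
    grid = maps[0].grid
    row, col = grid.locate(pts["x"].to_numpy(), pts["y"].to_numpy())
    inside = (row >= 0) & (row < grid.nrows) & (col >= 0) & (col < grid.ncols)
    row, col = row[inside], col[inside]
    labels = pts["final_label"].to_numpy(dtype=int)[inside]
    vals, counts = np.unique(labels, return_counts=True)
    small = vals[counts < 2]
    if small.size:
        raise ValueError(f"training classes with fewer than 2 points: {sorted(int(v) for v in small)}")

    x_train = encode_rf_features(maps, model, rows=row, cols=col)
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    rf.fit(x_train, labels)

    shape = maps[0].values.shape
    nodata = maps[0].nodata
    out = np.full(shape[0] * shape[1], nodata, dtype=np.int32)
    stack = np.stack([m.values for m in maps])
    nod = np.array([m.nodata for m in maps]).reshape(-1, 1, 1)
    any_vote = (stack != nod).any(axis=0).ravel()
    idx_all = np.nonzero(any_vote)[0]
    rr, cc = np.unravel_index(idx_all, shape)
    for start in range(0, idx_all.size, chunk):
        sl = slice(start, start + chunk)
        feats = encode_rf_features(maps, model, rows=rr[sl], cols=cc[sl])
        out[idx_all[sl]] = rf.predict(feats)
    return CategoricalRaster(
        values=out.reshape(shape),
        grid=grid,
        nodata=nodata,
        class_domain=frozenset(model.classes),
    )
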