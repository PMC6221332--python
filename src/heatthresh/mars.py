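"""Piecewise-linear adaptive spline regression (MARS) with hinge bases.

The regression model is

    y = b0 + sum_i b_i * h_i(x),        h_i(x) = prod_j hinge_ij(x)

where each hinge is ``max(x - t, 0)`` (upward) or ``max(t - x, 0)``
(downward) with knot ``t``, and terms are products of at most ``max_degree``
hinges on distinct variables. Fitting is the classical two-phase greedy
procedure: a forward pass that repeatedly adds the reflected hinge pair
(parent term x variable x knot) giving the largest least-squares RSS
decrease, then a backward pass that deletes terms one at a time and keeps
the visited subset minimising the generalized cross-validation score

    GCV = (RSS / n) / (1 - C / n)^2,    C = 1 + n_terms + penalty * n_knots.

Coefficients are refit by ordinary least squares at every step; candidate
knots are the observed covariate values with ``min_span`` observations
trimmed at each end. In the heatwave application the upward knots of the
pruned model are read off as morbidity thresholds (see
:mod:`heatthresh.thresholds`).

Two published fitted models for all-visitor standardized heat-illness
morbidity ship as fixtures: ``load_published_model("additive")`` (hinges on
AvgTmaxLag1 and Nindex1) and ``load_published_model("interaction")``
(second-order Tavg/AvgTmaxLag1 x Whum terms).

The statsmodels-style surface is :class:`MarsRegression` (model) whose
``fit()`` returns :class:`MarsResults`; the module-level functions
(:func:`forward_pass`, :func:`backward_prune`, :func:`fit`,
:func:`gcv_score`, ...) are the underlying engine.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CHUNK = 512  # candidate knots evaluated per vectorised block

UPWARD = "upward"
DOWNWARD = "downward"


# ---------------------------------------------------------------------------
# model representation


@dataclass(frozen=True)
class HingeFactor:
    """One hinge max(x - t, 0) (upward) or max(t - x, 0) (downward)."""

    variable: str
    knot: float
    direction: str  # UPWARD or DOWNWARD

    def __post_init__(self):
        if self.direction not in (UPWARD, DOWNWARD):
            raise ValueError(f"unknown hinge direction {self.direction!r}")
        if not math.isfinite(self.knot):
            raise ValueError("hinge knot must be finite")

    def value(self, x):
        x = np.asarray(x, dtype=float)
        if self.direction == UPWARD:
            return np.maximum(x - self.knot, 0.0)
        return np.maximum(self.knot - x, 0.0)

    def __str__(self):
        if self.direction == UPWARD:
            return f"max({self.variable} - {self.knot:g}, 0)"
        return f"max({self.knot:g} - {self.variable}, 0)"


def hinge_value(x, factor: HingeFactor):
    """Evaluate one hinge factor at x (scalar or array)."""
    v = factor.value(x)
    return float(v) if np.ndim(x) == 0 else v


@dataclass(frozen=True)
class BasisTerm:
    """Product of 1..max_degree hinge factors with its fitted coefficient."""

    factors: tuple[HingeFactor, ...]
    coefficient: float = 0.0

    def __post_init__(self):
        vars_ = [f.variable for f in self.factors]
        if len(set(vars_)) != len(vars_):
            raise ValueError("factors within one term must use distinct variables")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(f.variable for f in self.factors)

    def design_column(self, data: Mapping) -> np.ndarray:
        col = None
        for f in self.factors:
            v = f.value(np.asarray(data[f.variable], dtype=float))
            col = v if col is None else col * v
        return col

    def __str__(self):
        return " * ".join(str(f) for f in self.factors) or "1"


@dataclass
class MarsModel:
    """Portable fitted spline model: intercept + weighted hinge terms."""

    intercept: float
    terms: list[BasisTerm] = field(default_factory=list)
    n_obs: int | None = None
    gcv: float | None = None
    rss: float | None = None
    importance: list[tuple[str, float]] | None = None

    @property
    def variables(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.terms:
            for f in t.factors:
                seen.setdefault(f.variable, None)
        return list(seen)

    def predict(self, data):
        """Evaluate the model on a DataFrame, mapping of arrays, or scalars.

        Raises ``ValueError`` naming the first covariate absent from
        ``data``.
        """
        scalar = False
        if isinstance(data, pd.DataFrame):
            getter = data
        elif isinstance(data, Mapping):
            getter = data
            scalar = all(np.ndim(v) == 0 for v in data.values())
        else:
            raise TypeError("predict expects a DataFrame or mapping of covariates")
        for v in self.variables:
            if v not in getter:
                raise ValueError(f"missing covariate {v!r} in prediction input")
        n = 1
        if isinstance(getter, pd.DataFrame):
            n = len(getter)
        elif not scalar:
            n = len(np.asarray(next(iter(data.values()))))
        out = np.full(n, float(self.intercept))
        for t in self.terms:
            out = out + t.coefficient * np.broadcast_to(
                t.design_column(getter), (n,)
            )
        if scalar and n == 1 and not isinstance(getter, pd.DataFrame):
            return float(out[0])
        return out


def predict(model: MarsModel, data):
    """Functional alias for :meth:`MarsModel.predict`."""
    return model.predict(data)


# ---------------------------------------------------------------------------
# serialization


def serialize_model(model: MarsModel) -> dict:
    """Model document: plain dict, JSON-ready, lossless round trip."""
    return {
        "intercept": model.intercept,
        "terms": [
            {
                "coef": t.coefficient,
                "factors": [
                    {"variable": f.variable, "knot": f.knot, "direction": f.direction}
                    for f in t.factors
                ],
            }
            for t in model.terms
        ],
        "meta": {"n_obs": model.n_obs, "gcv": model.gcv, "rss": model.rss},
    }


def load_model(document) -> MarsModel:
    """Parse a model document (dict, JSON string, or path to a JSON file)."""
    if isinstance(document, (str, bytes)):
        s = str(document)
        if s.lstrip().startswith("{"):
            document = json.loads(s)
        else:
            with open(s) as fh:
                document = json.load(fh)
    if not isinstance(document, dict) or "intercept" not in document:
        raise ValueError("model document must be a dict with an 'intercept' key")
    terms = []
    for i, td in enumerate(document.get("terms", [])):
        factors = []
        for j, fd in enumerate(td.get("factors", [])):
            try:
                factors.append(
                    HingeFactor(
                        variable=str(fd["variable"]),
                        knot=float(fd["knot"]),
                        direction=fd.get("direction", ""),
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"term {i}, factor {j}: {exc}") from exc
        if not factors:
            raise ValueError(f"term {i}: at least one hinge factor required")
        terms.append(BasisTerm(tuple(factors), float(td["coef"])))
    meta = document.get("meta", {}) or {}
    return MarsModel(
        intercept=float(document["intercept"]),
        terms=terms,
        n_obs=meta.get("n_obs"),
        gcv=meta.get("gcv"),
        rss=meta.get("rss"),
    )


def save_model(model: MarsModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(serialize_model(model), fh, indent=1)


_PUBLISHED = {
    "additive": "hwwhole_additive.json",
    "interaction": "hwwhole_interaction.json",
}


def load_published_model(name: str = "additive") -> MarsModel:
    """Load one of the published all-visitor morbidity models.

    ``"additive"``: hinges on AvgTmaxLag1 (knot 32.95, both directions) and
    Nindex1 (knot 79.65). ``"interaction"``: the second-order model with
    Tavg x Whum and AvgTmaxLag1 x Whum products.
    """
    try:
        fname = _PUBLISHED[name]
    except KeyError:
        raise ValueError(f"unknown published model {name!r}; options: {sorted(_PUBLISHED)}")
    doc = resources.files("heatthresh.fixtures").joinpath(fname).read_text()
    return load_model(doc)


# ---------------------------------------------------------------------------
# fitting configuration


@dataclass
class FitConfig:
    """Knobs of the two-phase fit.

    max_terms
        Cap on basis functions including the intercept (a forward step adds
        a reflected pair, i.e. two terms).
    max_degree
        1 for additive models, 2 to allow pairwise hinge products.
    gcv_penalty
        Per-knot cost d in C = 1 + n_terms + d * n_knots; ``None`` selects
        3 when max_degree == 2, else 2.
    min_span
        Observations trimmed from each end of a covariate's sorted values
        before forming the candidate-knot grid.
    min_knot_gap
        Minimum number of candidate-grid positions between knots placed on
        the same variable; guards against pairs of near-coincident knots
        with huge cancelling coefficients that chase local noise. ``None``
        selects the standard adaptive value ~ -log2(-log(0.95)/(p*n))/2.5
        (about 7 grid steps at n=5000 with five covariates).
    rel_tol
        Forward pass stops when the best relative RSS improvement falls
        below this.
    forbidden_interaction_vars
        Variables barred from degree-2 terms (composite indices by
        default: they already mix temperature and humidity).
    exhaustive_prune_limit
        When the unpruned model has at most this many basis terms the
        backward pass visits every term subset (2^k refits) instead of
        only the greedy delete-one path, so the minimum-GCV subset is
        exact for small models; larger models fall back to the greedy
        path.
    seed
        Reserved for stochastic tie-shuffling; tie-breaking is
        deterministic (smaller variable index, then smaller knot) and the
        seed is unused by default.
    """

    max_terms: int = 21
    max_degree: int = 1
    gcv_penalty: float | None = None
    min_span: int = 5
    min_knot_gap: int | None = None
    exhaustive_prune_limit: int = 10
    rel_tol: float = 1e-5
    forbidden_interaction_vars: tuple[str, ...] = ("Nindex1", "Nindex2")
    seed: int | None = None

    def __post_init__(self):
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if self.max_degree not in (1, 2):
            raise ValueError("max_degree must be 1 or 2")
        if self.gcv_penalty is not None and self.gcv_penalty < 0:
            raise ValueError("gcv_penalty must be >= 0")

    @property
    def penalty(self) -> float:
        if self.gcv_penalty is not None:
            return float(self.gcv_penalty)
        return 3.0 if self.max_degree == 2 else 2.0


# ---------------------------------------------------------------------------
# GCV


def count_knots(terms: Iterable[BasisTerm]) -> int:
    """Distinct (variable, knot) pairs across the hinge factors of terms."""
    return len({(f.variable, f.knot) for t in terms for f in t.factors})


def gcv_score(rss: float, n: int, n_terms: int, n_knots: int, penalty: float) -> float:
    """GCV = (RSS/n) / (1 - C/n)^2 with C = 1 + n_terms + penalty*n_knots."""
    c = 1.0 + n_terms + penalty * n_knots
    if c >= n:
        raise ValueError(f"model saturated: effective parameters {c} >= n {n}")
    return (rss / n) / (1.0 - c / n) ** 2


# ---------------------------------------------------------------------------
# forward pass


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be two-dimensional")
    return arr, [f"x{i}" for i in range(arr.shape[1])]


def _candidate_knots(x: np.ndarray, min_span: int) -> np.ndarray:
    xs = np.sort(x)
    if min_span > 0:
        if xs.size <= 2 * min_span:
            return xs[:0]
        xs = xs[min_span : xs.size - min_span]
    return np.unique(xs)


def _design(terms: Sequence[tuple[HingeFactor, ...]], Xv, names) -> np.ndarray:
    cols = []
    idx = {v: i for i, v in enumerate(names)}
    for factors in terms:
        if not factors:
            cols.append(np.ones(Xv.shape[0]))
        else:
            c = np.ones(Xv.shape[0])
            for f in factors:
                c = c * f.value(Xv[:, idx[f.variable]])
            cols.append(c)
    return np.column_stack(cols)


def _lstsq(B, y):
    coef, _, rank, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid), rank


def _pair_rss_decrease(a, b, c, ru, rv, uu, vv):
    """RSS decrease from adding a reflected hinge pair, vectorised over knots.

    a, c are the squared norms of the pair columns after projecting out the
    current design; b their inner product; ru, rv their inner products with
    the residual; uu, vv the raw squared column norms (degeneracy scale).
    """
    tol_a = 1e-10 * (uu + 1e-300)
    tol_c = 1e-10 * (vv + 1e-300)
    det = a * c - b * b
    ok2 = det > 1e-10 * (a * c + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        dec2 = (c * ru**2 - 2.0 * b * ru * rv + a * rv**2) / det
        dec_u = np.where(a > tol_a, ru**2 / a, 0.0)
        dec_v = np.where(c > tol_c, rv**2 / c, 0.0)
    dec = np.where(ok2, dec2, np.maximum(dec_u, dec_v))
    return np.clip(np.nan_to_num(dec, nan=0.0, posinf=0.0, neginf=0.0), 0.0, None)


class _PairSearcher:
    """Vectorised search for the best reflected hinge pair to add.

    Exploits two facts to keep each forward step cheap: the downward member
    is an affine function of the upward one, ``(t-x)+ = (x-t)+ - x + t``,
    so only upward hinge columns are ever materialised; and the orthonormal
    basis Q of the design only gains columns between steps, so cached
    projections Q^T U stay valid and just grow new rows.
    """

    def __init__(self, Xv: np.ndarray, names: list[str], config: FitConfig):
        self.Xv = Xv
        self.names = names
        self.config = config
        self.knots = {
            v: _candidate_knots(Xv[:, i], config.min_span)
            for i, v in enumerate(names)
        }
        self._cache: dict[tuple[int, int], dict] = {}
        self._max_q = config.max_terms + 2
        self._buf: np.ndarray | None = None
        self._used: dict[str, list[float]] = {}
        if config.min_knot_gap is not None:
            self._gap = int(config.min_knot_gap)
        else:
            n, p = Xv.shape
            self._gap = max(
                1, int(-np.log2(-np.log1p(-0.05) / (max(p, 1) * n)) / 2.5)
            )

    def mark_used(self, variable: str, knot: float) -> None:
        self._used.setdefault(variable, []).append(knot)

    def _allowed_mask(self, var: str) -> np.ndarray | None:
        """Mask out candidates within min_knot_gap grid steps of used knots."""
        used = self._used.get(var)
        if not used:
            return None
        grid = self.knots[var]
        mask = np.ones(grid.size, dtype=bool)
        for k in used:
            j = int(np.searchsorted(grid, k))
            mask[max(0, j - self._gap) : j + self._gap + 1] = False
        return mask

    def _entry(self, pi: int, vi: int, K: int) -> dict:
        e = self._cache.get((pi, vi))
        if e is None:
            e = {
                "QU": np.empty((self._max_q, K)),
                "uu": np.empty(K),
                "uPx": np.empty(K),
                "uP": np.empty(K),
                "done": 0,
                "init": False,
            }
            self._cache[(pi, vi)] = e
        return e

    def best(self, terms, B, Q, r):
        """Return (dec, parent_idx, var_idx, knot) of the best pair, or None."""
        config = self.config
        forbidden = set(config.forbidden_interaction_vars)
        p = Q.shape[1]
        rss_cur = float(r @ r)
        tie_eps = 1e-9 * max(rss_cur, 1e-300)
        best = None
        for pi, parent in enumerate(terms):
            deg = len(parent)
            if deg >= config.max_degree:
                continue
            pvars = {f.variable for f in parent}
            if deg >= 1 and (pvars & forbidden):
                continue
            P = B[:, pi]
            PP = float(P @ P)
            rP = float(r @ P)
            qP = Q.T @ P
            for vi, var in enumerate(self.names):
                if var in pvars:
                    continue
                if deg >= 1 and var in forbidden:
                    continue
                knots = self.knots[var]
                K = knots.size
                if K == 0:
                    continue
                x = self.Xv[:, vi]
                allowed = self._allowed_mask(var)
                is_intercept = pi == 0
                Px = x if is_intercept else P * x
                PxPx = float(Px @ Px)
                PxP = float(Px @ P)
                rPx = float(r @ Px)
                qPx = Q.T @ Px
                e = self._entry(pi, vi, K)
                # one GEMM per chunk: residual row + the new basis rows
                M = np.column_stack([r, Q[:, e["done"] : p]])
                if self._buf is None or self._buf.shape[0] != len(x):
                    self._buf = np.empty((len(x), _CHUNK))
                for lo in range(0, K, _CHUNK):
                    hi = min(lo + _CHUNK, K)
                    t = knots[lo:hi]
                    U = self._buf[:, : hi - lo]
                    np.subtract(x[:, None], t[None, :], out=U)
                    np.maximum(U, 0.0, out=U)
                    if not is_intercept:
                        U *= P[:, None]
                    if not e["init"]:
                        e["uu"][lo:hi] = np.einsum("ij,ij->j", U, U)
                        e["uPx"][lo:hi] = Px @ U
                        e["uP"][lo:hi] = P @ U
                    RU = M.T @ U
                    e["QU"][e["done"] : p, lo:hi] = RU[1:]
                    ru = RU[0]
                    uu = e["uu"][lo:hi]
                    uPx = e["uPx"][lo:hi]
                    uP = e["uP"][lo:hi]
                    QU = e["QU"][:p, lo:hi]
                    QV = QU - qPx[:, None] + qP[:, None] * t[None, :]
                    vv = uu - 2.0 * uPx + 2.0 * t * uP + PxPx - 2.0 * t * PxP + t * t * PP
                    rv = ru - rPx + t * rP
                    a = uu - np.einsum("ij,ij->j", QU, QU)
                    c = vv - np.einsum("ij,ij->j", QV, QV)
                    b = (uu - uPx + t * uP) - np.einsum("ij,ij->j", QU, QV)
                    dec = _pair_rss_decrease(a, b, c, ru, rv, uu, vv)
                    if allowed is not None:
                        dec = np.where(allowed[lo:hi], dec, 0.0)
                    j = int(np.argmax(dec))
                    if best is None or dec[j] > best[0] + tie_eps:
                        best = (float(dec[j]), pi, vi, float(t[j]))
                e["init"] = True
                e["done"] = p
        return best


def _orth_append(Q: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Append col to the orthonormal basis Q (modified Gram-Schmidt, twice).

    Returns Q unchanged when col is numerically in span(Q).
    """
    nrm0 = np.linalg.norm(col)
    c = col - Q @ (Q.T @ col)
    c = c - Q @ (Q.T @ c)
    nrm = np.linalg.norm(c)
    if nrm0 == 0 or nrm < 1e-10 * nrm0:
        return Q
    return np.column_stack([Q, c / nrm])


def forward_pass(X, y, config: FitConfig | None = None):
    """Greedy forward hinge-pair selection.

    Returns ``(model, trace)`` where model is the unpruned :class:`MarsModel`
    and ``trace["forward"]`` records every accepted step (parent, variable,
    knot, RSS before/after).
    """
    config = config or FitConfig()
    Xv, names = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if n < 10:
        raise ValueError("need at least 10 observations")
    if np.isnan(Xv).any() or np.isnan(y).any():
        raise ValueError("missing values in X or y; drop them before fitting")

    terms: list[tuple[HingeFactor, ...]] = [()]  # intercept
    B = np.ones((n, 1))
    Q = B / np.sqrt(n)
    coef, rss, _ = _lstsq(B, y)
    trace: dict = {"forward": [], "prune": []}
    searcher = _PairSearcher(Xv, names, config)

    while len(terms) + 2 <= config.max_terms:
        # saturation guard for the GCV of the would-be model
        c_next = 1.0 + (len(terms) + 1) + config.penalty * (count_knots_raw(terms) + 1)
        if c_next >= n:
            break
        if rss <= 1e-12 * max(1.0, float(y @ y)):
            break
        r = y - Q @ (Q.T @ y)
        rss_cur = float(r @ r)

        best = searcher.best(terms, B, Q, r)
        if best is None:
            break
        dec, pi, vi, knot = best
        if rss_cur <= 0 or dec / rss_cur < config.rel_tol:
            break
        var = names[vi]
        parent = terms[pi]
        pair = (
            parent + (HingeFactor(var, knot, UPWARD),),
            parent + (HingeFactor(var, knot, DOWNWARD),),
        )
        B_try = np.column_stack(
            [B, _design([pair[0]], Xv, names), _design([pair[1]], Xv, names)]
        )
        coef_try, rss_try, rank = _lstsq(B_try, y)
        added = list(pair)
        if rank < B_try.shape[1]:
            # rank-deficient pair: keep whichever single member fits
            best_single = None
            for member in pair:
                B1 = np.column_stack([B, _design([member], Xv, names)])
                c1, r1, k1 = _lstsq(B1, y)
                if k1 == B1.shape[1] and (best_single is None or r1 < best_single[1]):
                    best_single = (member, r1, B1, c1)
            if best_single is None:
                logger.debug("rank-deficient candidate at %s@%g skipped", var, knot)
                break
            member, rss_try, B_try, coef_try = (
                best_single[0],
                best_single[1],
                best_single[2],
                best_single[3],
            )
            added = [member]
        terms.extend(added)
        searcher.mark_used(var, knot)
        for k in range(len(added)):
            Q = _orth_append(Q, B_try[:, B.shape[1] + k])
        B = B_try
        coef = coef_try
        trace["forward"].append(
            {
                "step": len(trace["forward"]) + 1,
                "parent": str(BasisTerm(parent)) if parent else "1",
                "variable": var,
                "knot": knot,
                "rss_before": rss,
                "rss_after": rss_try,
                "decrease": rss - rss_try,
            }
        )
        rss = rss_try

    model = _terms_to_model(terms, coef, n, rss, config)
    return model, trace


def count_knots_raw(terms: Sequence[tuple[HingeFactor, ...]]) -> int:
    return len({(f.variable, f.knot) for t in terms for f in t})


def _terms_to_model(terms, coef, n, rss, config) -> MarsModel:
    basis = [
        BasisTerm(f, float(c)) for f, c in zip(terms[1:], coef[1:], strict=True)
    ]
    n_knots = count_knots(basis)
    try:
        g = gcv_score(rss, n, len(basis), n_knots, config.penalty)
    except ValueError:
        g = float("inf")
    return MarsModel(
        intercept=float(coef[0]), terms=basis, n_obs=n, gcv=g, rss=float(rss)
    )


# ---------------------------------------------------------------------------
# backward pass


def backward_prune(model: MarsModel, X, y, config: FitConfig | None = None, trace=None):
    """Backward pruning; returns the visited subset with minimum GCV.

    At each step the term whose removal least increases the (refit) RSS is
    deleted; the intercept is never deleted. For small models (at most
    ``config.exhaustive_prune_limit`` terms) every term subset is visited
    in addition to the greedy path, making the selected subset the exact
    GCV minimiser. ``trace["prune"]``, when a trace dict is supplied,
    records the greedy path (each visited subset's GCV and the deleted
    term's variables), which drives the importance ranking.
    """
    config = config or FitConfig()
    Xv, names = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = Xv.shape[0]

    current = [t.factors for t in model.terms]

    def refit(subset):
        B = _design([()] + list(subset), Xv, names)
        coef, rss, _ = _lstsq(B, y)
        n_knots = len({(f.variable, f.knot) for fs in subset for f in fs})
        try:
            g = gcv_score(rss, n, len(subset), n_knots, config.penalty)
        except ValueError:
            g = float("inf")
        return coef, rss, g

    coef, rss, g = refit(current)
    path = [{"deleted": None, "gcv": g, "rss": rss, "n_terms": len(current)}]
    best = (g, list(current), coef, rss)

    while current:
        cands = []
        for i in range(len(current)):
            subset = current[:i] + current[i + 1 :]
            c_i, rss_i, g_i = refit(subset)
            cands.append((rss_i, i, subset, c_i, g_i))
        rss_i, i, subset, c_i, g_i = min(cands, key=lambda t: (t[0], t[1]))
        path.append(
            {
                "deleted": tuple(f.variable for f in current[i]),
                "gcv": g_i,
                "rss": rss_i,
                "n_terms": len(subset),
            }
        )
        current = subset
        if g_i < best[0]:
            best = (g_i, list(subset), c_i, rss_i)

    k = len(model.terms)
    if 0 < k <= config.exhaustive_prune_limit:
        import itertools

        all_factors = [t.factors for t in model.terms]
        for mask in itertools.product((1, 0), repeat=k):
            subset = [f for f, m in zip(all_factors, mask) if m]
            c_i, rss_i, g_i = refit(subset)
            if g_i < best[0]:
                best = (g_i, subset, c_i, rss_i)

    if trace is not None:
        trace["prune"] = path
    g, subset, coef, rss = best
    pruned = MarsModel(
        intercept=float(coef[0]),
        terms=[
            BasisTerm(f, float(c)) for f, c in zip(subset, coef[1:], strict=True)
        ],
        n_obs=n,
        gcv=g,
        rss=float(rss),
    )
    return pruned


# ---------------------------------------------------------------------------
# importance and the full fit


def variable_importance(model: MarsModel, trace) -> list[tuple[str, float]]:
    """Rank variables of the pruned model by GCV criterion.

    Walking the backward-pruning path, the GCV increase caused by deleting
    a term is credited to every variable appearing in that term; a
    variable's score is the sum of its credits. Ties break by total
    forward-pass RSS decrease, then variable name. Only variables retained
    in the final model are ranked.
    """
    final_vars = set(model.variables)
    if not final_vars:
        return []
    gscore: dict[str, float] = {v: 0.0 for v in final_vars}
    fscore: dict[str, float] = {v: 0.0 for v in final_vars}
    prev = None
    for entry in trace.get("prune", []):
        if prev is not None and entry["deleted"]:
            delta = entry["gcv"] - prev["gcv"]
            for v in entry["deleted"]:
                if v in gscore:
                    gscore[v] += delta
        prev = entry
    for step in trace.get("forward", []):
        v = step["variable"]
        if v in fscore:
            fscore[v] += step["decrease"]
    ranked = sorted(
        final_vars, key=lambda v: (-gscore[v], -fscore[v], v)
    )
    return [(v, gscore[v]) for v in ranked]


def fit(X, y, config: FitConfig | None = None) -> MarsModel:
    """Forward pass, backward prune, importance; the full fitting recipe."""
    config = config or FitConfig()
    unpruned, trace = forward_pass(X, y, config)
    pruned = backward_prune(unpruned, X, y, config, trace)
    pruned.importance = variable_importance(pruned, trace)
    pruned._trace = trace  # type: ignore[attr-defined]
    return pruned


# ---------------------------------------------------------------------------
# statsmodels-style surface


class MarsRegression:
    """Adaptive spline regression model bound to data.

    Parameters
    ----------
    endog : array_like
        Response (continuous; e.g. population-standardized daily morbidity).
    exog : DataFrame or 2-D array
        Covariates; column names become model variable names.
    config : FitConfig, optional

    Rows with any missing covariate or response are dropped before fitting
    (with a logged count).
    """

    def __init__(self, endog, exog, config: FitConfig | None = None):
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog, dtype=float))
            exog.columns = [f"x{i}" for i in range(exog.shape[1])]
        y = pd.Series(np.asarray(endog, dtype=float).ravel())
        if len(y) != len(exog):
            raise ValueError("endog and exog lengths differ")
        mask = exog.notna().all(axis=1) & y.notna()
        dropped = int((~mask).sum())
        if dropped:
            logger.info("dropped %d rows with missing covariates/response", dropped)
        self.exog = exog.loc[mask.values].reset_index(drop=True)
        self.endog = y[mask.values].reset_index(drop=True)
        self.config = config or FitConfig()
        self.n_dropped = dropped

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        features: Sequence[str] | None = None,
        config: FitConfig | None = None,
    ) -> "MarsRegression":
        if features is None:
            features = [
                c
                for c in data.columns
                if c != response and pd.api.types.is_numeric_dtype(data[c])
            ]
        missing = [c for c in list(features) + [response] if c not in data.columns]
        if missing:
            raise ValueError(f"columns not in data: {missing}")
        return cls(data[response], data[list(features)], config=config)

    def fit(self) -> "MarsResults":
        model = fit(self.exog, self.endog.to_numpy(), self.config)
        return MarsResults(self, model, getattr(model, "_trace", {}))


class MarsResults:
    """Results wrapper: fitted spline, diagnostics, thresholds, plotting."""

    def __init__(self, model: MarsRegression, spline: MarsModel, trace: dict):
        self.model = model
        self.spline = spline
        self.trace = trace

    # -- basic quantities ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        names = ["(Intercept)"] + [str(t) for t in self.spline.terms]
        vals = [self.spline.intercept] + [t.coefficient for t in self.spline.terms]
        return pd.Series(vals, index=names, name="coefficient")

    @property
    def gcv(self) -> float:
        return self.spline.gcv

    @property
    def rss(self) -> float:
        return self.spline.rss

    @property
    def rsquared(self) -> float:
        y = self.model.endog.to_numpy()
        tss = float(((y - y.mean()) ** 2).sum())
        return 1.0 - self.rss / tss if tss > 0 else float("nan")

    @property
    def importance(self) -> list[tuple[str, float]]:
        return self.spline.importance or []

    def predict(self, data=None):
        if data is None:
            data = self.model.exog
        return self.spline.predict(data)

    # -- thresholds ---------------------------------------------------------
    def thresholds(self):
        """Heatwave thresholds: knots of positive upward degree-1 hinges."""
        from .thresholds import extract_thresholds

        return extract_thresholds(self.spline)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        s = self.spline
        lines = []
        lines.append("Adaptive spline regression (hinge basis)")
        lines.append("=" * 58)
        lines.append(
            f"n_obs: {s.n_obs}    terms: {len(s.terms)}    "
            f"knots: {count_knots(s.terms)}"
        )
        lines.append(
            f"RSS: {s.rss:.6g}    GCV: {s.gcv:.6g}    R^2: {self.rsquared:.4f}"
        )
        lines.append("-" * 58)
        lines.append(f"{'term':<44}{'coef':>14}")
        lines.append(f"{'(Intercept)':<44}{s.intercept:>14.5g}")
        for t in s.terms:
            lines.append(f"{str(t):<44}{t.coefficient:>14.5g}")
        if s.importance:
            lines.append("-" * 58)
            lines.append("variable importance (GCV criterion)")
            for rank, (v, score) in enumerate(s.importance, 1):
                lines.append(f"  #{rank} {v:<20} {score:.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def save(self, path) -> None:
        save_model(self.spline, path)

    # -- plotting -----------------------------------------------------------
    def plot_partial(self, variable: str, ax=None, n_points: int = 200):
        """Partial-dependence sweep of one covariate, others at medians."""
        import matplotlib.pyplot as plt

        if variable not in self.model.exog.columns:
            raise ValueError(f"unknown covariate {variable!r}")
        if ax is None:
            _, ax = plt.subplots()
        med = self.model.exog.median()
        grid = np.linspace(
            self.model.exog[variable].min(), self.model.exog[variable].max(), n_points
        )
        frame = pd.DataFrame({c: np.full(n_points, med[c]) for c in self.model.exog})
        frame[variable] = grid
        ax.plot(grid, self.spline.predict(frame))
        ax.set_xlabel(variable)
        ax.set_ylabel("predicted outcome")
        return ax
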