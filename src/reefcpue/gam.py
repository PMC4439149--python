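"""Gaussian additive model with penalized spline smooths and a random intercept.

The model is

    y_i = alpha + sum_s f_s(x_si) + b_{g(i)} + e_i,   e ~ N(0, sigma^2),
    b_g ~ N(0, sigma_b^2)

with each f_s a penalized cubic regression spline (B-spline basis on
equally spaced knots, second-order difference penalty) under a sum-to-zero
constraint, and the grouped intercepts b implemented as ridge-penalized
dummies — the classical mixed-model equivalence (lambda = sigma^2 /
sigma_b^2).  Smoothing parameters are chosen by minimizing GCV.  Each
smooth's penalty null space after the constraint is the linear function,
so a smooth shrinks toward a straight line (edf -> 1) when the data carry
no curvature.

Reported per-term quantities follow the conventions for penalized smooths:
edf is the trace of the hat-matrix block, F is the Wald-type statistic
(f_hat' f_hat / edf) / sigma_hat^2 with an F(edf, n - edf_total) reference
— approximate, as usual for penalized regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, null_space


# ---------------------------------------------------------------------------
# terms
# ---------------------------------------------------------------------------

@dataclass
class SmoothTerm:
    """Penalized spline smooth of one covariate."""

    name: str
    k: int = 10          # basis dimension before the sum-to-zero constraint
    degree: int = 3

    def __post_init__(self) -> None:
        if self.k < self.degree + 2:
            raise ValueError("basis dimension too small for the spline degree")


@dataclass
class LinearTerm:
    name: str


@dataclass
class RandomIntercept:
    name: str


@dataclass
class _Block:
    term: object
    cols: slice
    penalty: np.ndarray | None       # in block coordinates; None = unpenalized
    knots: np.ndarray | None = None
    constraint: np.ndarray | None = None   # Z: basis -> constrained coords
    levels: np.ndarray | None = None
    x_range: tuple[float, float] | None = None
    degenerate: str | None = None


def _spline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    return BSpline.design_matrix(x, knots, degree,
                                 extrapolate=False).toarray()


def _spline_knots(lo: float, hi: float, k: int, degree: int) -> np.ndarray:
    n_interior = k - degree - 1
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class AdditiveModel:
    """Penalized additive Gaussian model on a dataframe.

    Parameters
    ----------
    data : DataFrame with the response and covariates.
    response : response column name.
    terms : sequence of SmoothTerm / LinearTerm / RandomIntercept.
    """

    def __init__(self, data: pd.DataFrame, response: str, terms) -> None:
        self.data = data.reset_index(drop=True)
        self.response = response
        self.terms = list(terms)
        self.y = self.data[response].to_numpy(dtype=float)
        if not np.all(np.isfinite(self.y)):
            raise ValueError("response contains non-finite values")
        self.n = len(self.y)
        self._build_design()

    def _build_design(self) -> None:
        n = self.n
        cols: list[np.ndarray] = [np.ones((n, 1))]
        blocks: list[_Block] = []
        notes: list[str] = []
        start = 1
        for term in self.terms:
            if isinstance(term, SmoothTerm):
                x = self.data[term.name].to_numpy(dtype=float)
                lo, hi = float(np.min(x)), float(np.max(x))
                if hi <= lo:
                    notes.append(f"smooth '{term.name}' dropped: constant covariate")
                    blocks.append(_Block(term, slice(start, start), None,
                                         degenerate="constant"))
                    continue
                k = min(term.k, max(5, len(np.unique(x))))
                knots = _spline_knots(lo, hi, k, term.degree)
                B = _spline_design(x, knots, term.degree)
                c = B.mean(axis=0)
                Z = null_space(c[None, :])            # (k, k-1)
                Xj = B @ Z
                D = np.diff(np.eye(k), n=2, axis=0)
                S = Z.T @ (D.T @ D) @ Z
                width = Xj.shape[1]
                blocks.append(_Block(term, slice(start, start + width), S,
                                     knots=knots, constraint=Z,
                                     x_range=(lo, hi)))
                cols.append(Xj)
                start += width
            elif isinstance(term, LinearTerm):
                x = self.data[term.name].to_numpy(dtype=float)
                if np.ptp(x) == 0:
                    notes.append(f"linear '{term.name}' dropped: constant covariate")
                    blocks.append(_Block(term, slice(start, start), None,
                                         degenerate="constant"))
                    continue
                cols.append((x - x.mean())[:, None])
                blocks.append(_Block(term, slice(start, start + 1), None,
                                     x_range=(float(x.min()), float(x.max()))))
                start += 1
            elif isinstance(term, RandomIntercept):
                levels, codes = np.unique(self.data[term.name].to_numpy(),
                                          return_inverse=True)
                if len(levels) < 2:
                    raise ValueError("random intercept needs >= 2 levels")
                G = np.zeros((n, len(levels)))
                G[np.arange(n), codes] = 1.0
                width = len(levels)
                blocks.append(_Block(term, slice(start, start + width),
                                     np.eye(width), levels=levels))
                cols.append(G)
                start += width
            else:
                raise TypeError(f"unknown term type {type(term)!r}")
        self.X = np.hstack(cols)
        self.blocks = blocks
        self.notes = notes
        self.p = self.X.shape[1]
        self._XtX = self.X.T @ self.X
        self._Xty = self.X.T @ self.y
        self._yty = float(self.y @ self.y)
        self._penalties: list[dict] = []
        self._build_penalty_units()

    def _build_penalty_units(self) -> None:
        """One penalty unit per smoothing parameter.

        Each smooth contributes its curvature penalty and (for
        ``fit(select=True)``) a rank-1 shrinkage penalty on the penalty's
        null space, so a term can be penalized out entirely (the
        double-penalty approach to smooth-term selection).  The random
        intercept contributes an identity penalty.
        """
        self._smooth_units = []
        self._shrink_units = []
        for b in self.blocks:
            if b.penalty is None or b.degenerate:
                continue
            ev, vec = np.linalg.eigh(b.penalty)
            pos = ev > max(ev.max(), 1.0) * 1e-10
            rank = int(pos.sum())
            logdet = float(np.sum(np.log(ev[pos])))
            kind = ("random" if isinstance(b.term, RandomIntercept)
                    else "smooth")
            self._smooth_units.append({"block": b, "mat": b.penalty,
                                       "rank": rank, "logdet": logdet,
                                       "kind": kind})
            if kind == "smooth" and rank < b.penalty.shape[0]:
                nullv = vec[:, ~pos]                 # orthonormal null basis
                self._shrink_units.append({"block": b,
                                           "mat": nullv @ nullv.T,
                                           "rank": nullv.shape[1],
                                           "logdet": 0.0,
                                           "kind": "shrink"})

    # -- fitting ------------------------------------------------------------

    def _assemble(self, lambdas: np.ndarray) -> np.ndarray:
        A = self._XtX.copy()
        for lam, u in zip(lambdas, self._penalties):
            c = u["block"].cols
            A[c, c] += lam * u["mat"]
        return A

    def _solve(self, lambdas: np.ndarray):
        A = self._assemble(lambdas)
        # tiny ridge guards exact collinearity (dummies vs intercept)
        A[np.diag_indices_from(A)] += 1e-10
        cf = cho_factor(A)
        beta = cho_solve(cf, self._Xty)
        H_tr_mat = cho_solve(cf, self._XtX)          # A^{-1} X'X
        rss = self._yty - 2 * beta @ self._Xty + beta @ self._XtX @ beta
        rss = max(rss, 1e-12)
        return beta, cf, H_tr_mat, rss

    def _gcv(self, rho: np.ndarray) -> float:
        lambdas = np.exp(np.clip(rho, -18.0, 18.0))
        _, _, Hm, rss = self._solve(lambdas)
        edf = float(np.trace(Hm))
        denom = max(self.n - edf, 1e-6)
        return self.n * rss / denom ** 2

    def _reml(self, rho: np.ndarray) -> float:
        """Negative restricted log-likelihood (constants dropped).

        2 V_r = (n - Mp) log(D / (n - Mp)) + log|X'X + S_lambda|
                - sum_j (rank_j log lambda_j + log|S_j|_+)
        with D = RSS + beta' S_lambda beta and Mp the count of
        unpenalized coefficients.
        """
        lambdas = np.exp(np.clip(rho, -18.0, 18.0))
        try:
            beta, cf, _, rss = self._solve(lambdas)
        except np.linalg.LinAlgError:
            return np.inf
        pen = 0.0
        for lam, u in zip(lambdas, self._penalties):
            bj = beta[u["block"].cols]
            pen += lam * float(bj @ u["mat"] @ bj)
        d = max(rss + pen, 1e-300)
        mp = self.p - sum(u["rank"] for u in self._penalties)
        logdet_a = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_s = sum(u["rank"] * np.log(lam) + u["logdet"]
                       for lam, u in zip(lambdas, self._penalties))
        nmp = self.n - mp
        return 0.5 * (nmp * np.log(d / nmp) + logdet_a - logdet_s)

    def fit(self, lambdas: np.ndarray | None = None, method: str = "REML",
            select: bool = False, maxiter: int = 400) -> "AdditiveResults":
        """Estimate coefficients; smoothing parameters by REML (or GCV).

        ``select=True`` adds the null-space shrinkage penalties so REML can
        remove an unneeded smooth entirely (edf toward 0) — the mode meant
        for AIC-based term selection.
        """
        self._penalties = (self._smooth_units + self._shrink_units
                           if select else list(self._smooth_units))
        n_pen = len(self._penalties)
        if lambdas is None:
            if method not in {"REML", "GCV"}:
                raise ValueError("method must be 'REML' or 'GCV'")
            objective = self._reml if method == "REML" else self._gcv
            if n_pen == 0:
                lambdas = np.empty(0)
            else:
                best, best_val = None, np.inf
                for x0 in (np.zeros(n_pen), np.full(n_pen, 5.0)):
                    res = optimize.minimize(
                        objective, x0, method="Nelder-Mead",
                        options={"maxiter": maxiter, "xatol": 1e-3,
                                 "fatol": 1e-10})
                    if res.fun < best_val:
                        best, best_val = res.x, res.fun
                lambdas = np.exp(np.clip(best, -18.0, 18.0))
        else:
            lambdas = np.asarray(lambdas, dtype=float)
            if len(lambdas) != n_pen:
                raise ValueError("one lambda per penalty required")
        beta, cf, Hm, rss = self._solve(lambdas)
        tau = self._corrected_dof(lambdas, beta, cf, Hm, rss)
        return AdditiveResults(self, beta, lambdas, Hm, rss, cf, tau)

    def _corrected_dof(self, lambdas, beta, cf, Hm, rss) -> float:
        """Smoothing-uncertainty corrected dof for AIC.

        tau = tr(F) + tr(X'X J V_rho J') / sigma^2 with J = d beta / d rho
        (analytic) and V_rho the inverse REML Hessian (finite differences).
        Falls back to tr(F) when no penalty is active.
        """
        edf = float(np.trace(Hm))
        k = len(self._penalties)
        if k == 0:
            return edf
        sigma2 = rss / max(self.n - edf, 1.0)
        # J: d beta / d rho_j = -lambda_j A^{-1} S_j beta
        J = np.zeros((self.p, k))
        for j, (lam, u) in enumerate(zip(lambdas, self._penalties)):
            g = np.zeros(self.p)
            c = u["block"].cols
            g[c] = lam * (u["mat"] @ beta[c])
            J[:, j] = -cho_solve(cf, g)
        # REML Hessian by central differences
        rho = np.log(lambdas)
        h = 1e-3
        H = np.zeros((k, k))
        f0 = self._reml(rho)
        if not np.isfinite(f0):
            return edf
        for a in range(k):
            for b in range(a, k):
                ea = np.zeros(k); ea[a] = h
                eb = np.zeros(k); eb[b] = h
                if a == b:
                    H[a, a] = (self._reml(rho + ea) - 2 * f0
                               + self._reml(rho - ea)) / h ** 2
                else:
                    H[a, b] = H[b, a] = (
                        self._reml(rho + ea + eb) - self._reml(rho + ea - eb)
                        - self._reml(rho - ea + eb) + self._reml(rho - ea - eb)
                    ) / (4 * h ** 2)
        if not np.all(np.isfinite(H)):
            return edf
        ev, vec = np.linalg.eigh(H)
        tol = max(ev.max(), 1.0) * 1e-6
        inv_ev = np.where(ev > tol, 1.0 / np.maximum(ev, tol), 0.0)
        v_rho = (vec * inv_ev) @ vec.T
        extra = float(np.trace(self._XtX @ J @ v_rho @ J.T)) / sigma2
        return edf + max(extra, 0.0)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class AdditiveResults:
    """Fitted additive model: estimates, edf, tests, AIC, partial effects."""

    def __init__(self, model: AdditiveModel, beta, lambdas, Hm, rss, cf,
                 tau: float | None = None):
        self.model = model
        self.params = beta
        self.lambdas = lambdas
        self._Hm = Hm
        self.rss = float(rss)
        n = model.n
        self.edf_total = float(np.trace(Hm))
        self.resid_df = n - self.edf_total
        self.scale = self.rss / self.resid_df          # sigma_hat^2
        self.fittedvalues = model.X @ beta
        self.resid = model.y - self.fittedvalues
        # Bayesian posterior covariance of the coefficients
        self.cov_params = cho_solve(cf, np.eye(model.p)) * self.scale
        sigma2_ml = self.rss / n
        # AIC dof: smoothing-uncertainty corrected tau when available
        self.aic_dof = float(tau) if tau is not None else self.edf_total
        self.aic = (n * np.log(2 * np.pi * sigma2_ml) + n
                    + 2.0 * (self.aic_dof + 1.0))
        self._term_table = self._build_term_table()

    # -- per-term quantities -------------------------------------------------

    def _pen_index(self, block) -> int | None:
        for k, u in enumerate(self.model._penalties):
            if u["block"] is block and u["kind"] != "shrink":
                return k
        return None

    def _build_term_table(self) -> pd.DataFrame:
        rows = []
        n = self.model.n
        for b in self.model.blocks:
            name = b.term.name
            if b.degenerate:
                rows.append({"term": name, "type": "dropped", "edf": 0.0,
                             "F": np.nan, "p": np.nan})
                continue
            edf = float(np.trace(self._Hm[b.cols, b.cols]))
            if isinstance(b.term, RandomIntercept):
                k = self._pen_index(b)
                lam = self.lambdas[k]
                sd_b = float(np.sqrt(self.scale / lam)) if lam > 0 else np.inf
                rows.append({"term": f"{name} (random intercept)",
                             "type": "random", "edf": edf, "F": np.nan,
                             "p": np.nan, "sd": sd_b})
                continue
            beta_j = self.params[b.cols]
            XtX_j = self.model._XtX[b.cols, b.cols]
            edf_eff = max(edf, 1e-8)
            F = float(beta_j @ XtX_j @ beta_j / edf_eff / self.scale)
            p = float(stats.f.sf(F, edf_eff, self.resid_df))
            kind = "smooth" if isinstance(b.term, SmoothTerm) else "linear"
            rows.append({"term": name, "type": kind, "edf": edf, "F": F,
                         "p": p})
        return pd.DataFrame(rows)

    @property
    def term_table(self) -> pd.DataFrame:
        return self._term_table.copy()

    @property
    def response(self) -> np.ndarray:
        return self.model.y

    @property
    def n_terms(self) -> int:
        return len(self.model.terms)

    def edf(self, term: str) -> float:
        t = self._term_table
        row = t[t["term"].str.startswith(term)]
        if row.empty:
            raise KeyError(term)
        return float(row["edf"].iloc[0])

    # -- partial effects -----------------------------------------------------

    def partial_effects(self, term: str, n_points: int = 100,
                        values: np.ndarray | None = None) -> pd.DataFrame:
        """Centred smooth effect on a grid with 95% pointwise intervals.

        Columns: value, effect, lower, upper.  Evaluation outside the
        observed covariate range is refused (no extrapolation).
        """
        block = next((b for b in self.model.blocks
                      if b.term.name == term and not b.degenerate), None)
        if block is None:
            raise KeyError(f"term {term!r} not in fit")
        lo, hi = block.x_range
        if values is None:
            values = np.linspace(lo, hi, n_points)
        else:
            values = np.asarray(values, dtype=float)
            if values.min() < lo - 1e-12 or values.max() > hi + 1e-12:
                raise ValueError("evaluation outside the observed covariate "
                                 "range is refused")
        if isinstance(block.term, SmoothTerm):
            B = _spline_design(np.clip(values, lo, hi), block.knots,
                               block.term.degree)
            Xg = B @ block.constraint
        else:  # linear
            xobs = self.model.data[term].to_numpy(dtype=float)
            Xg = (values - xobs.mean())[:, None]
        beta_j = self.params[block.cols]
        V = self.cov_params[block.cols, block.cols]
        effect = Xg @ beta_j
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        return pd.DataFrame({
            "value": values,
            "effect": effect,
            "lower": effect - 1.96 * se,
            "upper": effect + 1.96 * se,
        })

    def rug(self, term: str) -> np.ndarray:
        """Observed covariate values (for rug plots alongside the smooth)."""
        return self.model.data[term].to_numpy(dtype=float)

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Gaussian additive model (penalized splines, REML)",
            f"n = {self.model.n}    edf(total) = {self.edf_total:.2f}    "
            f"scale = {self.scale:.4f}    AIC = {self.aic:.2f}",
            "",
            f"{'term':<28}{'edf':>8}{'F':>10}{'p':>12}",
        ]
        for row in self._term_table.itertuples(index=False):
            if row.type == "random":
                lines.append(f"{row.term:<28}{row.edf:>8.2f}"
                             f"{'':>10}{'':>12}  sd = {row.sd:.3f}")
            elif row.type == "dropped":
                lines.append(f"{row.term:<28}{'dropped (constant)':>30}")
            else:
                p_str = "<0.001" if row.p < 1e-3 else f"{row.p:.3f}"
                lines.append(f"{row.term:<28}{row.edf:>8.2f}{row.F:>10.2f}"
                             f"{p_str:>12}")
        for note in self.model.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def select_model(candidates: list[AdditiveResults]) -> AdditiveResults:
    """Pick the candidate with minimal AIC; ties go to fewer terms.

    All candidates must be fitted to the same response rows; candidates
    without a finite AIC are excluded with a warning.
    """
    import warnings

    if not candidates:
        raise ValueError("no candidates")
    ref = candidates[0].response
    for c in candidates[1:]:
        if len(c.response) != len(ref) or not np.allclose(c.response, ref):
            raise ValueError("candidates do not share the same response rows")
    usable = []
    for c in candidates:
        if np.isfinite(c.aic):
            usable.append(c)
        else:
            warnings.warn("candidate with non-finite AIC excluded")
    if not usable:
        raise ValueError("no candidate with a finite AIC")
    best_aic = min(c.aic for c in usable)
    tied = [c for c in usable if c.aic <= best_aic + 1e-9]
    return min(tied, key=lambda c: c.n_terms)
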