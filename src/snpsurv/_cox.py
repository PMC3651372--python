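"""Risk-set bookkeeping shared by the score tests and the lasso fitter.

Everything here works in "sorted coordinates": samples ordered by
decreasing observed time, so that the risk set at any event time is a
prefix of the ordering and the sums ``s_k(t) = sum_i z_i^k Y_i(t)`` become
prefix sums. Tied times share a risk set (Breslow convention), which the
``searchsorted`` index below implements: the risk set of an event at time
``t`` contains every sample with ``X_j >= t``, including simultaneous
events.
"""
from __future__ import annotations

import numpy as np

__all__ = ["RiskSetCache"]


class RiskSetCache:
    """Pre-sorted structures for Breslow partial-likelihood computations.

    Attributes
    ----------
    order
        Permutation sorting samples by decreasing observed time (stable).
    event_pos
        Positions (in sorted coordinates) of the samples with an event.
    event_end
        For each event, the index of the last sorted sample belonging to
        its risk set; prefix sums evaluated there give ``s_k`` at that
        event time.
    """

    def __init__(self, surv) -> None:
        times = surv.times
        n = times.size
        order = np.argsort(-times, kind="stable")
        t_sorted = times[order]
        n_at_risk = n - np.searchsorted(np.sort(times), t_sorted, side="left")
        riskset_end = n_at_risk - 1
        ev_sorted = np.asarray(surv.events)[order].astype(bool)
        self.n = n
        self.order = order
        self.event_pos = np.nonzero(ev_sorted)[0]
        self.event_end = riskset_end[self.event_pos]
        self.n_events = int(self.event_pos.size)
        if self.n_events == 0:
            raise ValueError(
                "no observed events: partial-likelihood statistics are undefined"
            )

    def sort_rows(self, Z: np.ndarray) -> np.ndarray:
        """Reorder covariate rows into the cache's sorted coordinates."""
        return np.asarray(Z, dtype=float)[self.order]

    # ------------------------------------------------------------------
    # Null-hypothesis (beta = 0) moments used by the score tests. Under
    # H0 the weights exp(eta) are all 1, so s_0(t) is just the risk-set
    # size and the s_k are unweighted prefix sums.
    # ------------------------------------------------------------------
    def null_moments(self, Z_sorted: np.ndarray):
        """Score statistic W and its null variance, column-wise.

        ``W = n^{-1/2} sum_i int {z_i - s1/s0} dN_i`` and
        ``var = n^{-1} sum_i int {s2/s0 - s1^2/s0^2} dN_i``.
        """
        Z = Z_sorted
        c1 = np.cumsum(Z, axis=0)[self.event_end]
        c2 = np.cumsum(Z * Z, axis=0)[self.event_end]
        s0 = (self.event_end + 1.0)[:, None]
        zbar = c1 / s0
        W = (Z[self.event_pos] - zbar).sum(axis=0) / np.sqrt(self.n)
        var = (c2 / s0 - zbar**2).sum(axis=0) / self.n
        return W, var

    def null_cross(self, Za_sorted: np.ndarray, Zb_sorted: np.ndarray):
        """Null covariance of the score statistics of two scorings.

        ``n^{-1} sum_i int {z_ai - s_a1/s_0}{z_bi - s_b1/s_0} (Y_i/Y) dN``,
        which reduces to ``n^{-1} sum_events [s_ab/s0 - s_a1 s_b1 / s0^2]``
        with ``s_ab(t) = sum_i z_ai z_bi Y_i(t)``.
        """
        s0 = (self.event_end + 1.0)[:, None]
        cab = np.cumsum(Za_sorted * Zb_sorted, axis=0)[self.event_end]
        za = np.cumsum(Za_sorted, axis=0)[self.event_end] / s0
        zb = np.cumsum(Zb_sorted, axis=0)[self.event_end] / s0
        return (cab / s0 - za * zb).sum(axis=0) / self.n

    # ------------------------------------------------------------------
    # Weighted (general beta) quantities for the penalized fitter.
    # ------------------------------------------------------------------
    def loglik(self, eta_sorted: np.ndarray) -> float:
        """Breslow partial log-likelihood from the sorted linear predictor."""
        mx = eta_sorted.max()
        cw = np.cumsum(np.exp(eta_sorted - mx))
        return float(
            eta_sorted[self.event_pos].sum()
            - self.n_events * mx
            - np.log(cw[self.event_end]).sum()
        )

    def grad(self, Z_sorted: np.ndarray, eta_sorted: np.ndarray) -> np.ndarray:
        """Gradient of the partial log-likelihood with respect to beta.

        Uses the residual form ``Z^T (dN - exp(eta) * A)`` where ``A_k``
        accumulates ``1/S0`` over the event times whose risk set contains
        sample ``k``.
        """
        mx = eta_sorted.max()
        w = np.exp(eta_sorted - mx)
        cw = np.cumsum(w)
        contrib = np.bincount(
            self.event_end, weights=1.0 / cw[self.event_end], minlength=self.n
        )
        A = contrib[::-1].cumsum()[::-1]
        r = -w * A
        r[self.event_pos] += 1.0
        return Z_sorted.T @ r

    def dir_derivs(self, eta_sorted, d_sorted, d_event_sum, t):
        """First/second derivative of ``l(eta + t d)`` along a direction."""
        e = eta_sorted + t * d_sorted
        mx = e.max()
        w = np.exp(e - mx)
        s0 = np.cumsum(w)[self.event_end]
        m1 = np.cumsum(w * d_sorted)[self.event_end] / s0
        m2 = np.cumsum(w * d_sorted * d_sorted)[self.event_end] / s0
        d1 = d_event_sum - m1.sum()
        d2 = -(m2 - m1 * m1).sum()
        return d1, d2
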