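"""Archimedean copula families for dependent-censoring survival models.

An Archimedean copula is defined through a generator ``phi``: a continuous,
strictly decreasing function on (0, 1] with ``phi(1) = 0`` and
``phi(v) -> inf`` as ``v -> 0+``.  The bivariate copula is

    C(v, w) = phi_inv(phi(v) + phi(w)).

Three one-parameter families are provided, together with the independence
copula (generator ``-log t``):

========  =============================================  =================
family    generator phi_alpha(t)                          Kendall's tau
========  =============================================  =================
clayton   (t^-alpha - 1) / alpha,  alpha > 0              alpha/(alpha+2)
gumbel    (-log t)^(alpha+1),      alpha >= 0             alpha/(alpha+1)
frank     -log[(e^(-alpha t)-1)/(e^(-alpha)-1)], a != 0   1 - 4(1-D1(a))/a
========  =============================================  =================

where ``D1`` is the first Debye function.  Clayton and Gumbel admit only
positive dependence; Frank admits negative dependence (negative alpha).
All three families contain independence as the limit ``alpha -> 0``
(``alpha = 0`` exactly for Gumbel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "ArchimedeanCopula",
    "CopulaParameterError",
    "FAMILIES",
    "debye1",
]

#: Generator values at or above this cap are treated as infinite:
#: ``generator_inverse`` maps them to exactly 0.
PHI_CAP = 1e300

#: |alpha| below this is routed to the independence generator for the
#: clayton/frank families (both converge to -log t; the exact formulas
#: suffer catastrophic cancellation near 0).
ALPHA_EPS = 1e-8

FAMILIES = ("clayton", "gumbel", "frank", "independence")


class CopulaParameterError(ValueError):
    """Invalid (family, alpha) combination or unattainable tau."""


def debye1(x: float) -> float:
    """First Debye function D1(x) = (1/x) * int_0^x t/(e^t - 1) dt.

    Evaluated by adaptive quadrature; the integrand is defined by its
    limit (= 1) at t = 0.  D1(0) = 1.
    """
    if x == 0.0:
        return 1.0

    def integrand(t: float) -> float:
        if abs(t) < 1e-12:
            return 1.0 - t / 2.0
        return t / math.expm1(t)

    val, _ = integrate.quad(integrand, 0.0, x, epsrel=1e-10, epsabs=0.0, limit=200)
    return val / x


@dataclass(frozen=True)
class ArchimedeanCopula:
    """An Archimedean copula: a family tag plus dependence parameter alpha.

    Parameters
    ----------
    family
        One of ``"clayton"``, ``"gumbel"``, ``"frank"``, ``"independence"``.
    alpha
        Dependence parameter.  Constraints: clayton requires ``alpha > 0``,
        gumbel ``alpha >= 0``, frank ``alpha != 0``; independence takes no
        parameter (alpha fixed at 0).  Clayton/frank alpha within 1e-8 of 0
        is treated as independence.
    """

    family: str
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise CopulaParameterError(
                f"unknown copula family {self.family!r}; choose from {FAMILIES}"
            )
        a = float(self.alpha)
        if not math.isfinite(a):
            raise CopulaParameterError("alpha must be finite")
        if self.family == "clayton" and a < 0:
            raise CopulaParameterError("clayton requires alpha > 0")
        if self.family == "gumbel" and a < 0:
            raise CopulaParameterError("gumbel requires alpha >= 0")
        if self.family == "independence" and a != 0.0:
            raise CopulaParameterError("independence copula has no parameter")
        object.__setattr__(self, "alpha", a)

    # ------------------------------------------------------------------
    @property
    def _effective_family(self) -> str:
        """Family after routing near-zero clayton/frank (and gumbel 0) to
        the shared independence generator."""
        if self.family == "gumbel" and self.alpha == 0.0:
            return "independence"
        if self.family in ("clayton", "frank") and abs(self.alpha) < ALPHA_EPS:
            return "independence"
        return self.family

    # ------------------------------------------------------------------
    def generator(self, v):
        """Generator phi_alpha(v) for v in [0, 1].

        Returns the infinite cap for v = 0.  Accepts scalars or arrays.
        """
        v_arr = np.asarray(v, dtype=float)
        if np.any((v_arr < 0.0) | (v_arr > 1.0)):
            raise ValueError("generator argument must lie in [0, 1]")
        fam = self._effective_family
        a = self.alpha
        with np.errstate(divide="ignore", over="ignore"):
            if fam == "independence":
                out = -np.log(v_arr)
            elif fam == "clayton":
                # exp/log form avoids overflow in v**-a for tiny v, large a
                out = np.where(
                    v_arr > 0.0,
                    np.expm1(-a * np.log(np.maximum(v_arr, 1e-320))) / a,
                    np.inf,
                )
            elif fam == "gumbel":
                out = (-np.log(v_arr)) ** (a + 1.0)
            else:  # frank
                out = -np.log(np.expm1(-a * v_arr) / np.expm1(-a))
        out = np.where(np.isfinite(out) & (out < PHI_CAP), out, np.inf)
        out = np.where(v_arr == 1.0, 0.0, out)
        if np.ndim(v) == 0:
            return float(out)
        return out

    def generator_inverse(self, s):
        """Inverse generator phi_alpha^{-1}(s) for s >= 0.

        Maps 0 to 1 and the infinite sentinel (or anything >= the cap) to
        exactly 0; monotone non-increasing.
        """
        s_arr = np.asarray(s, dtype=float)
        if np.any(s_arr < 0.0):
            raise ValueError("inverse generator argument must be >= 0")
        fam = self._effective_family
        a = self.alpha
        finite = s_arr < PHI_CAP
        s_safe = np.where(finite, s_arr, 0.0)
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            if fam == "independence":
                out = np.exp(-s_safe)
            elif fam == "clayton":
                out = np.exp(-np.log1p(a * s_safe) / a)
            elif fam == "gumbel":
                out = np.exp(-(s_safe ** (1.0 / (a + 1.0))))
            else:  # frank
                out = -np.log1p(np.exp(-s_safe) * np.expm1(-a)) / a
        out = np.where(finite, out, 0.0)
        out = np.where(s_arr == 0.0, 1.0, out)  # phi_inv(0) = 1 exactly
        out = np.clip(out, 0.0, 1.0)
        if np.ndim(s) == 0:
            return float(out)
        return out

    def generator_derivative(self, v):
        """phi_alpha'(v), the (negative) derivative of the generator.

        Used by the conditional-inversion copula sampler.
        """
        v_arr = np.asarray(v, dtype=float)
        fam = self._effective_family
        a = self.alpha
        with np.errstate(divide="ignore", over="ignore"):
            if fam == "independence":
                out = -1.0 / v_arr
            elif fam == "clayton":
                out = -(v_arr ** (-a - 1.0))
            elif fam == "gumbel":
                out = -(a + 1.0) * (-np.log(v_arr)) ** a / v_arr
            else:  # frank
                out = -a / np.expm1(a * v_arr)
        if np.ndim(v) == 0:
            return float(out)
        return out

    # ------------------------------------------------------------------
    def kendall_tau(self) -> float:
        """Kendall's tau implied by the copula.

        Closed forms for clayton (``alpha/(alpha+2)``) and gumbel
        (``alpha/(alpha+1)``); for frank, ``1 - (4/alpha)(1 - D1(alpha))``
        by quadrature (odd in alpha).  Independence: 0.
        """
        fam = self._effective_family
        a = self.alpha
        if fam == "independence":
            return 0.0
        if fam == "clayton":
            return a / (a + 2.0)
        if fam == "gumbel":
            return a / (a + 1.0)
        return 1.0 - (4.0 / a) * (1.0 - debye1(a))

    def cdf(self, v, w):
        """Copula C(v, w) = phi_inv(phi(v) + phi(w))."""
        return self.generator_inverse(
            np.asarray(self.generator(v)) + np.asarray(self.generator(w))
        )


# ----------------------------------------------------------------------
_TAU_RANGES = {
    "clayton": "(0, 1)",
    "gumbel": "[0, 1)",
    "frank": "(-1, 1) excluding 0",
}


def alpha_from_tau(family: str, tau: float) -> float:
    """Invert the tau(alpha) relation for a family.

    clayton: ``alpha = 2 tau / (1 - tau)``; gumbel: ``alpha = tau/(1-tau)``;
    frank: numerical root of ``kendall_tau(alpha) = tau`` (|residual| <
    1e-8).  Raises :class:`CopulaParameterError` when tau is outside the
    family's attainable range.
    """
    tau = float(tau)
    if family == "independence":
        if tau != 0.0:
            raise CopulaParameterError("independence copula has tau = 0 only")
        return 0.0
    if family == "clayton":
        if not 0.0 < tau < 1.0:
            raise CopulaParameterError(
                f"clayton tau must lie in {_TAU_RANGES['clayton']}, got {tau}"
            )
        return 2.0 * tau / (1.0 - tau)
    if family == "gumbel":
        if not 0.0 <= tau < 1.0:
            raise CopulaParameterError(
                f"gumbel tau must lie in {_TAU_RANGES['gumbel']}, got {tau}"
            )
        return tau / (1.0 - tau)
    if family == "frank":
        if not -1.0 < tau < 1.0 or tau == 0.0:
            raise CopulaParameterError(
                f"frank tau must lie in {_TAU_RANGES['frank']}, got {tau}"
            )
        # tau is odd in alpha; solve for |tau| on alpha > 0 then restore sign
        target = abs(tau)

        def f(a: float) -> float:
            return ArchimedeanCopula("frank", a).kendall_tau() - target

        lo, hi = 1e-6, 1.0
        while f(hi) < 0.0:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover - tau < 1 always brackets
                raise CopulaParameterError(f"cannot bracket frank tau {tau}")
        root = optimize.brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
        return math.copysign(root, tau)
    raise CopulaParameterError(f"unknown copula family {family!r}")
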