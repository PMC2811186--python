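"""Candidate functional forms for pressure-response relationships.

A *utility threshold* is the pressure level at which small changes in a
human-induced pressure (fishing rate, habitat degradation, pollution ...)
produce disproportionately large changes in an ecosystem attribute.  The
threshold is defined mathematically from the shape of the fitted
attribute-pressure curve:

* ``piecewise`` (continuous broken-stick): the breakpoint ``Pt`` where the
  two line segments intersect.  The slope (first derivative) switches from
  ``m1`` to ``m2`` at that pressure.
* ``sigmoidal``: the inflection point ``ln(1/c2)/c3``, where the first
  derivative is extremal and the second derivative changes sign.
* ``linear``, ``negexp`` (negative exponential) and ``parabolic`` admit no
  objectively defined utility threshold — their derivative never switches
  abruptly — and serve only as competitors in model selection.

All pressures are expressed on a relative [0, 1] axis (0 = least stressed,
1 = most stressed); see :func:`ecothresh.attributes.rescale_pressure`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, fields
from typing import Optional, Union

import numpy as np

__all__ = [
    "FORM_ORDER",
    "PARAM_COUNT",
    "LinearParams",
    "PiecewiseParams",
    "SigmoidParams",
    "NegExpParams",
    "ParabolicParams",
    "ResponseModel",
    "FormParamsMismatch",
    "AmbiguousDerivative",
]

#: Canonical ordering of candidate forms (also the deterministic tie-break
#: order in model selection, after parameter count).
FORM_ORDER = ("linear", "piecewise", "sigmoidal", "negexp", "parabolic")

#: Number of estimated parameters per form *including* the error variance,
#: as counted in the AICc small-sample correction.
PARAM_COUNT = {
    "linear": 3,
    "piecewise": 5,
    "sigmoidal": 5,
    "negexp": 4,
    "parabolic": 4,
}


class FormParamsMismatch(TypeError):
    """Raised when a model's ``form`` string and params type disagree."""


class AmbiguousDerivative(ValueError):
    """Raised when the one-sided derivative of a broken-stick model is
    requested exactly at the breakpoint without specifying a side."""


@dataclass(frozen=True)
class LinearParams:
    """y = b0 + m0 * P"""

    b0: float
    m0: float


@dataclass(frozen=True)
class PiecewiseParams:
    """Continuous broken-stick: two lines intersecting at the breakpoint.

    y = b1 + m1*P            for P <  Pt
    y = b1 + m1*Pt + m2*(P-Pt)  for P >= Pt

    Continuity at ``Pt`` holds by construction.  ``Pt`` is the utility
    threshold and must lie inside the observed pressure range when fitted.
    """

    Pt: float
    b1: float
    m1: float
    m2: float


@dataclass(frozen=True)
class SigmoidParams:
    """y = c1 + (c0 - c1) / (1 + c2 * exp(c3 * P))

    ``c0`` approximates the value at zero pressure, ``c1`` the asymptote
    under maximal pressure.  Requires c2 > 0 and c3 > 0 so that the
    inflection ln(1/c2)/c3 is finite.
    """

    c0: float
    c1: float
    c2: float
    c3: float


@dataclass(frozen=True)
class NegExpParams:
    """y = a0 + a1 * exp(a2 * P)  (a2 < 0 gives exponential decay)"""

    a0: float
    a1: float
    a2: float


@dataclass(frozen=True)
class ParabolicParams:
    """y = d0 + d1 * P + d2 * P**2"""

    d0: float
    d1: float
    d2: float


Params = Union[LinearParams, PiecewiseParams, SigmoidParams, NegExpParams, ParabolicParams]

_PARAM_TYPES = {
    "linear": LinearParams,
    "piecewise": PiecewiseParams,
    "sigmoidal": SigmoidParams,
    "negexp": NegExpParams,
    "parabolic": ParabolicParams,
}
_FORM_OF_TYPE = {v: k for k, v in _PARAM_TYPES.items()}


@dataclass(frozen=True)
class ResponseModel:
    """A candidate response form together with its parameter values."""

    form: str
    params: Params

    def __post_init__(self) -> None:
        if self.form not in _PARAM_TYPES:
            raise FormParamsMismatch(f"unknown form {self.form!r}; expected one of {FORM_ORDER}")
        expected = _PARAM_TYPES[self.form]
        if not isinstance(self.params, expected):
            raise FormParamsMismatch(
                f"form {self.form!r} requires {expected.__name__}, "
                f"got {type(self.params).__name__}"
            )
        vals = [getattr(self.params, f.name) for f in fields(self.params)]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite parameter in {self.params}")
        if self.form == "sigmoidal":
            p = self.params
            if p.c2 <= 0 or p.c3 <= 0:
                raise ValueError(f"sigmoid requires c2 > 0 and c3 > 0, got c2={p.c2}, c3={p.c3}")

    # ------------------------------------------------------------------
    def evaluate(self, P):
        """Evaluate the curve at pressure(s) ``P``.

        At exactly ``P == Pt`` the broken-stick uses the right segment
        (the two agree there by continuity).
        """
        P = np.asarray(P, dtype=float)
        if not np.all(np.isfinite(P)):
            raise ValueError("pressure must be finite")
        p = self.params
        if self.form == "linear":
            out = p.b0 + p.m0 * P
        elif self.form == "piecewise":
            out = np.where(
                P < p.Pt,
                p.b1 + p.m1 * P,
                p.b1 + p.m1 * p.Pt + p.m2 * (P - p.Pt),
            )
        elif self.form == "sigmoidal":
            out = p.c1 + (p.c0 - p.c1) / (1.0 + p.c2 * np.exp(p.c3 * P))
        elif self.form == "negexp":
            out = p.a0 + p.a1 * np.exp(p.a2 * P)
        else:  # parabolic
            out = p.d0 + p.d1 * P + p.d2 * P * P
        return out if out.ndim else float(out)

    __call__ = evaluate

    # ------------------------------------------------------------------
    def first_derivative(self, P, side: Optional[str] = None):
        """Analytic first derivative dy/dP at pressure(s) ``P``.

        For the broken-stick model the derivative is undefined exactly at
        the breakpoint; pass ``side='left'`` or ``side='right'`` to obtain
        the one-sided slope there.
        """
        P = np.asarray(P, dtype=float)
        if not np.all(np.isfinite(P)):
            raise ValueError("pressure must be finite")
        p = self.params
        if self.form == "linear":
            out = np.full_like(P, p.m0)
        elif self.form == "piecewise":
            at_break = P == p.Pt
            if np.any(at_break) and side is None:
                raise AmbiguousDerivative(
                    f"slope of the broken-stick model is ambiguous exactly at the "
                    f"breakpoint Pt={p.Pt}; pass side='left' or side='right'"
                )
            if side not in (None, "left", "right"):
                raise ValueError(f"side must be 'left' or 'right', got {side!r}")
            left = P < p.Pt
            if side == "left":
                left = P <= p.Pt
            out = np.where(left, p.m1, p.m2)
        elif self.form == "sigmoidal":
            e = p.c2 * np.exp(p.c3 * P)
            out = -(p.c0 - p.c1) * p.c3 * e / (1.0 + e) ** 2
        elif self.form == "negexp":
            out = p.a1 * p.a2 * np.exp(p.a2 * P)
        else:  # parabolic
            out = p.d1 + 2.0 * p.d2 * P
        return out if out.ndim else float(out)

    def second_derivative(self, P):
        """Analytic second derivative; used to verify the sigmoid inflection."""
        P = np.asarray(P, dtype=float)
        p = self.params
        if self.form == "linear":
            out = np.zeros_like(P)
        elif self.form == "piecewise":
            out = np.zeros_like(P)  # zero on each open segment
        elif self.form == "sigmoidal":
            e = p.c2 * np.exp(p.c3 * P)
            out = -(p.c0 - p.c1) * p.c3**2 * e * (1.0 - e) / (1.0 + e) ** 3
        elif self.form == "negexp":
            out = p.a1 * p.a2**2 * np.exp(p.a2 * P)
        else:
            out = np.full_like(P, 2.0 * p.d2)
        return out if out.ndim else float(out)

    # ------------------------------------------------------------------
    def threshold(self) -> Optional[float]:
        """The utility threshold pressure, or None when the form admits none.

        * broken-stick: the fitted breakpoint ``Pt``;
        * sigmoid: the inflection ``ln(1/c2)/c3``, where the second
          derivative crosses zero and the slope is steepest;
        * linear / negative-exponential / parabolic: ``None`` — their
          curvature never switches, so no threshold is objectively defined.
        """
        p = self.params
        if self.form == "piecewise":
            return float(p.Pt)
        if self.form == "sigmoidal":
            if p.c2 <= 0 or p.c3 == 0:
                raise ValueError("sigmoid inflection requires c2 > 0 and c3 != 0")
            return float(math.log(1.0 / p.c2) / p.c3)
        return None

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        return {"form": self.form, "params": asdict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "ResponseModel":
        form = d["form"]
        if form not in _PARAM_TYPES:
            raise FormParamsMismatch(f"unknown form {form!r}")
        params = _PARAM_TYPES[form](**d["params"])
        return cls(form=form, params=params)

    def param_names(self) -> tuple:
        return tuple(f.name for f in fields(self.params))

    def param_values(self) -> np.ndarray:
        return np.array([getattr(self.params, f.name) for f in fields(self.params)], dtype=float)


def make_model(form: str, *values: float) -> ResponseModel:
    """Construct a :class:`ResponseModel` from positional parameter values."""
    ptype = _PARAM_TYPES.get(form)
    if ptype is None:
        raise FormParamsMismatch(f"unknown form {form!r}")
    return ResponseModel(form=form, params=ptype(*values))
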