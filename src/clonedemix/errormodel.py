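"""Error-model configuration shared by preprocessing and the solver.

Three models decide when a measured quantity is indistinguishable from
zero:

* ``exact``  — strict float comparison at absolute tolerance ``atol``;
* ``bound``  — interval arithmetic: ``|d| <= eps_i + sum(eps_children)``;
* ``normal`` — two-sided Gaussian test at confidence level ``1 - alpha``:
  ``|d| <= z_{1-alpha/2} * sqrt(eps_i**2 + sum(eps_children**2))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .exceptions import InputError
from .model import ATOL

KINDS = ("exact", "bound", "normal")


@dataclass(frozen=True)
class ErrorModelConfig:
    kind: str = "exact"
    alpha: float = 0.05
    atol: float = ATOL

    def __post_init__(self):
        if self.kind not in KINDS:
            raise InputError(f"unknown error model {self.kind!r}; expected one of {KINDS}")
        if not 0 < self.alpha < 1:
            raise InputError(f"alpha must be in (0, 1), got {self.alpha}")

    @property
    def z(self) -> float:
        """Two-sided normal quantile ``z_{1-alpha/2}``."""
        return float(norm.ppf(1 - self.alpha / 2))

    # -- allowances -----------------------------------------------------

    def sum_allowance(self, eps_parent: float, eps_children_sum: float,
                      eps_children_sq_sum: float) -> float:
        """Half-width of the acceptance region for
        ``y[i] - sum(y[children])`` given the parent and child errors."""
        if self.kind == "exact":
            return self.atol
        if self.kind == "bound":
            return eps_parent + eps_children_sum + self.atol
        return self.z * math.sqrt(eps_parent ** 2 + eps_children_sq_sum) + self.atol

    def allowance(self, eps_parent: float, eps_children) -> float:
        """Convenience wrapper taking an iterable of child errors."""
        eps_children = list(eps_children)
        return self.sum_allowance(
            eps_parent, sum(eps_children), sum(e * e for e in eps_children)
        )

    def pair_allowance(self, eps_a: float, eps_b: float) -> float:
        """Half-width for deciding whether two frequencies are
        indistinguishable (used by frequency clustering)."""
        if self.kind == "exact":
            return self.atol
        if self.kind == "bound":
            return eps_a + eps_b + self.atol
        return self.z * math.sqrt(eps_a ** 2 + eps_b ** 2) + self.atol

    def single_allowance(self, eps: float) -> float:
        """Half-width for comparing one measurement against a constant
        (used by the homogeneous-entry removal rule)."""
        if self.kind == "exact":
            return self.atol
        if self.kind == "bound":
            return eps + self.atol
        return self.z * eps + self.atol

    # -- decisions ------------------------------------------------------

    def is_zero(self, value: float, allowance: float) -> bool:
        return abs(value) <= allowance

    def indistinguishable(self, y_a: float, eps_a: float, y_b: float, eps_b: float) -> bool:
        return abs(y_a - y_b) <= self.pair_allowance(eps_a, eps_b)


EXACT = ErrorModelConfig("exact")
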