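"""Prior settings for coefficients and model space.

The coefficient prior is a Zellner-type g prior on the included
coefficients, with improper flat priors on the intercept and on log
sigma. The scale g controls how strongly conditional posterior means are
shrunk toward zero (shrinkage factor g/(1+g)) and how heavily large
models are penalised in the marginal likelihood. The model prior is
uniform over the 2^s candidate subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigError

__all__ = ["PriorSettings", "G_RULES"]

G_RULES = ("uip", "bric", "fixed")


@dataclass(frozen=True)
class PriorSettings:
    """Coefficient-prior scale rule plus the (uniform) model prior.

    g_rule
        ``"uip"``   unit-information prior, g = n (default);
        ``"bric"``  benchmark rule, g = max(n, s^2);
        ``"fixed"`` use the explicit value in ``g``.
    g
        Explicit positive scale; required when ``g_rule="fixed"``,
        ignored otherwise.
    """

    g_rule: str = "uip"
    g: float | None = None

    def __post_init__(self) -> None:
        if self.g_rule not in G_RULES:
            raise ConfigError(f"unknown g_rule '{self.g_rule}'; choose from {G_RULES}")
        if self.g_rule == "fixed":
            if self.g is None or not self.g > 0:
                raise ConfigError("g_rule='fixed' requires a positive g")
        elif self.g is not None:
            raise ConfigError(f"g must be None unless g_rule='fixed' (got {self.g})")

    def resolve_g(self, n: int, s: int) -> float:
        """Concrete g for a table with n rows and s candidate covariates."""
        if self.g_rule == "uip":
            return float(n)
        if self.g_rule == "bric":
            return float(max(n, s * s))
        return float(self.g)
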