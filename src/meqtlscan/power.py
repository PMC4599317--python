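"""Power for testing one term of a multiple linear regression.

Follows the Cohen f^2 framework: for a test of u numerator df against v
denominator df at level alpha with effect size f^2, power is the upper tail
of a noncentral F(u, v, lambda) beyond the central-F critical value, with
lambda = f^2 * (u + v + 1). An alternative convention lambda = f^2 * n is
available behind a flag; for a single tested term with n = u + v + 1 the
two coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .exceptions import DomainError

__all__ = ["PowerSpec", "power_f2", "power_from_r2"]


@dataclass(frozen=True)
class PowerSpec:
    u: int  # numerator df
    v: int  # denominator df
    f2: float  # Cohen effect size, r2 / (1 - r2)
    alpha: float = 0.05

    def validate(self) -> None:
        if self.u < 1 or self.v < 1:
            raise DomainError("u and v must be >= 1")
        if self.f2 < 0:
            raise DomainError("f2 must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise DomainError("alpha must be in (0, 1)")


def power_f2(spec: PowerSpec, ncp_convention: str = "u+v+1",
             n: int | None = None) -> float:
    """P(F' > F_crit) for F' ~ noncentral F(u, v, lambda).

    ``ncp_convention="u+v+1"`` (default) sets lambda = f2 * (u + v + 1);
    ``"n"`` sets lambda = f2 * n (supply the sample size), which differs
    whenever the model holds more terms than the one tested. At f2 = 0 the
    result equals alpha exactly.
    """
    spec.validate()
    crit = stats.f.isf(spec.alpha, spec.u, spec.v)
    if spec.f2 == 0.0:
        return float(spec.alpha)
    if ncp_convention == "u+v+1":
        lam = spec.f2 * (spec.u + spec.v + 1)
    elif ncp_convention == "n":
        if n is None:
            raise DomainError("ncp_convention='n' requires the sample size n")
        lam = spec.f2 * n
    else:
        raise DomainError(f"unknown ncp convention {ncp_convention!r}")
    return float(stats.ncf.sf(crit, spec.u, spec.v, lam))


def power_from_r2(partial_r2: float, n: int, n_model_terms: int,
                  alpha: float = 0.05) -> float:
    """Replication power for a scan hit with the given partial R^2.

    Converts r^2 to f^2 = r^2 / (1 - r^2) and evaluates power for a 1-df
    test with v = n - n_model_terms - 1 denominator df.
    """
    if not (0.0 <= partial_r2 < 1.0):
        raise DomainError("partial_r2 must be in [0, 1)")
    if n <= n_model_terms + 1:
        raise DomainError("n must exceed n_model_terms + 1")
    f2 = partial_r2 / (1.0 - partial_r2)
    return power_f2(PowerSpec(u=1, v=n - n_model_terms - 1, f2=f2, alpha=alpha))
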