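"""Shared result container for statistical tests."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class TestResult:
    """Outcome of a single statistical test.

    Attributes
    ----------
    statistic_name : str
        Name of the test statistic (e.g. ``"rayleigh_Z"``).
    statistic : float
        Observed value of the statistic.
    p_value : float
        Two-sided unless the method note says otherwise; always in [0, 1].
    n : int
        Sample size (first sample for two-sample tests).
    m : int, optional
        Second-sample size for two-sample tests.
    method_note : str
        How the p-value was obtained (asymptotic series, permutation count,
        Monte-Carlo draws, seed, chosen branch of an adaptive gate, ...).
    extra : dict
        Auxiliary quantities (group medians, tie counts, ...).
    """

    statistic_name: str
    statistic: float
    p_value: float
    n: int
    m: int | None = None
    method_note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value!r} outside [0, 1]")

    def summary(self) -> dict:
        out = {
            "statistic_name": self.statistic_name,
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n": int(self.n),
            "method_note": self.method_note,
        }
        if self.m is not None:
            out["m"] = int(self.m)
        if self.extra:
            out["extra"] = {
                k: (float(v) if hasattr(v, "__float__") else v)
                for k, v in self.extra.items()
            }
        return out
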