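"""Sample-size significance thresholds for allele frequencies.

With a sample of N individuals (2N gene copies), low allele frequencies are
poorly estimated, and a detected allele may still be statistically
*nonsignificant*: zero lies inside the confidence interval of its frequency.
Three sampling models give the threshold below which that happens at the 95%
level:

* **Model I** (standard normal, two-tail): smallest p with
  ``p - z*sqrt(p(1-p)/(2N)) > 0``, i.e. ``p* = z^2/(2N + z^2)`` with z = 2
  ("two standard deviations").  At N = 50 this is 3.85%: every smaller
  estimate is not significantly different from zero.
* **Model II** (normal, one-tail): same closed form with the one-tail
  quantile z1 = 1.645.  Marked approximate — it does not reproduce the
  published one-tail column (e.g. 2.63 vs the printed 2.75 at N = 50), whose
  exact construction is undocumented; it is provided for completeness only.
* **Model III** (exact binomial): p* solving ``(1-p)^(2N) = alpha``, i.e.
  ``p* = 1 - alpha^(1/(2N))`` — the frequency below which the probability of
  observing zero copies exceeds alpha.

Because of this, analyses should avoid discussing the "number of alleles
present" or "the presence or absence of given alleles" in samples of the
usual sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from hlapop.errors import SampleSizeWarning

MODELS = ("I_normal_two_tail", "II_normal_one_tail", "III_exact_binomial")

#: minimal recommended number of individuals per sample
MINIMUM_SAMPLE_SIZE = 100

_MODEL_ALIASES = {
    "I": "I_normal_two_tail",
    "II": "II_normal_one_tail",
    "III": "III_exact_binomial",
}


@dataclass
class ThresholdQuery:
    """A threshold request: N individuals, sampling model, significance level
    alpha and (models I/II) the normal quantile z."""

    N: int
    model: str = "I_normal_two_tail"
    alpha: float = 0.05
    z: float = 2.0          # model I: "two standard deviations"
    z_one_tail: float = 1.645

    def __post_init__(self):
        self.model = _MODEL_ALIASES.get(self.model, self.model)
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")


@dataclass
class Threshold:
    percent: float            # rounded half away from zero, 2 decimals
    percent_unrounded: float
    proportion: float         # unrounded, on [0,1]
    query: ThresholdQuery


def _round_half_away(x: float, ndigits: int = 2) -> float:
    scale = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)


def frequency_threshold(q: ThresholdQuery | int, model: str | None = None) -> Threshold:
    """Allele-frequency threshold (percent) below which the confidence
    interval contains zero for a sample of ``q.N`` individuals.

    Accepts a :class:`ThresholdQuery` or a bare N (with ``model``).
    """
    if not isinstance(q, ThresholdQuery):
        q = ThresholdQuery(N=int(q), model=model or "I_normal_two_tail")
    two_n = 2 * q.N
    if q.model == "I_normal_two_tail":
        p = q.z ** 2 / (two_n + q.z ** 2)
    elif q.model == "II_normal_one_tail":
        p = q.z_one_tail ** 2 / (two_n + q.z_one_tail ** 2)
    else:  # exact binomial
        p = 1.0 - q.alpha ** (1.0 / two_n)
    percent = 100.0 * p
    return Threshold(
        percent=_round_half_away(percent, 2),
        percent_unrounded=percent,
        proportion=p,
        query=q,
    )


DEFAULT_NS = (30, 50, 100, 150, 200, 500)


def threshold_table(Ns=DEFAULT_NS, alpha: float = 0.05) -> pd.DataFrame:
    """Threshold matrix (percent, 2 decimals): one row per N, one column per
    sampling model.  Thresholds decrease monotonically with N."""
    rows = {}
    for N in Ns:
        rows[N] = [
            frequency_threshold(ThresholdQuery(N=N, model=m, alpha=alpha)).percent
            for m in MODELS
        ]
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=["model_I", "model_II", "model_III"]
    )
    df.index.name = "N"
    return df


@dataclass
class SampleSizeAdvisory:
    N: int
    ok: bool
    message: str


def minimum_sample_check(N: int) -> SampleSizeAdvisory:
    """Advise on sample size: below 100 individuals a warning is emitted;
    larger samples detect more alleles and estimate frequencies better."""
    if N < MINIMUM_SAMPLE_SIZE:
        msg = (
            f"sample of {N} individuals is below the recommended minimal "
            f"threshold of {MINIMUM_SAMPLE_SIZE}; keep sample sizes as close "
            "as possible to this threshold"
        )
        warnings.warn(msg, SampleSizeWarning, stacklevel=2)
        return SampleSizeAdvisory(N=N, ok=False, message=msg)
    return SampleSizeAdvisory(
        N=N,
        ok=True,
        message=(
            f"sample of {N} individuals meets the recommended minimum; note "
            "that more individuals per sample will detect more alleles and "
            "give better frequency estimates"
        ),
    )
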