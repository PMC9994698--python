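"""Pre- vs post-release sex-ratio comparison.

Sex of headstarted juveniles is *presumed* from egg incubation temperature
(the release protocol targets 1:1.5 male:female); none of the animals are
mature, so morphology cannot sex them.  The post-release ratio is taken from
first captures in the 2018-2020 trapping surveys and compared to the
pre-release ratio with a Pearson chi-square goodness-of-fit test (df = 1, no
continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .encounters import SURVEY_YEARS


@dataclass(frozen=True)
class SexRatioTest:
    observed: tuple[int, int]          # (males, females)
    expected_ratio: tuple[float, float]
    expected: tuple[float, float]
    chi2: float
    df: int
    p_value: float


def parse_ratio(text: str | tuple[float, float]) -> tuple[float, float]:
    """Parse 'a:b' male:female odds."""
    if isinstance(text, str):
        a, b = (float(x) for x in text.split(":"))
    else:
        a, b = float(text[0]), float(text[1])
    if a <= 0 or b <= 0:
        raise ValueError("ratio shares must be positive")
    return a, b


def first_captures(
    captures: pd.DataFrame,
    survey_years: tuple[int, ...] = SURVEY_YEARS,
) -> tuple[int, int]:
    """Count presumed (males, females) from first captures in survey years.

    ``captures`` needs columns ``individual_id``, ``year``, ``sex`` ('M'/'F').
    Each individual is counted once, at its earliest capture; unknown sex
    labels are excluded with a warning.
    """
    if captures.empty:
        return (0, 0)
    df = captures[captures["year"].isin(survey_years)]
    if df.empty:
        return (0, 0)
    firsts = df.sort_values("year", kind="stable").drop_duplicates(
        "individual_id", keep="first"
    )
    sexes = firsts["sex"].astype(str).str.upper()
    unknown = ~sexes.isin(["M", "F"])
    if unknown.any():
        warnings.warn(
            f"excluding {int(unknown.sum())} capture(s) with unknown sex label",
            stacklevel=2,
        )
    return int((sexes == "M").sum()), int((sexes == "F").sum())


def chi2_gof(
    observed: tuple[int, int],
    expected_ratio: str | tuple[float, float] = "1:1.5",
) -> SexRatioTest:
    """Pearson chi-square test of observed counts against an expected ratio."""
    a, b = parse_ratio(expected_ratio)
    m, f = int(observed[0]), int(observed[1])
    n = m + f
    if n <= 0:
        raise ValueError("no observations")
    exp = (n * a / (a + b), n * b / (a + b))
    if exp[0] <= 0 or exp[1] <= 0:
        raise ValueError("expected counts must be positive")
    stat = (m - exp[0]) ** 2 / exp[0] + (f - exp[1]) ** 2 / exp[1]
    p = float(chi2.sf(stat, df=1))
    return SexRatioTest(
        observed=(m, f),
        expected_ratio=(a, b),
        expected=exp,
        chi2=float(stat),
        df=1,
        p_value=p,
    )
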