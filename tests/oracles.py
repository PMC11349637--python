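"""Independent oracles used by the test suite.

These deliberately bypass the package's computation paths: constants are
re-read straight from the shipped YAML files, the relative risk is
re-summed in a different (sorted) order, and the absolute risk is
integrated numerically on a fine midpoint grid instead of the closed
form.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import yaml

RAW_FILES = {
    "white": "white.yaml",
    "black": "black_hazards_synthetic.yaml",
    "hispanic": "hispanic_hazards_synthetic.yaml",
    "asian_pacific_islander": "asian_pacific_islander_hazards_synthetic.yaml",
    "other_unknown": "white.yaml",
}


def load_raw_constants(race: str = "white") -> dict:
    text = (
        resources.files("chestscreen")
        .joinpath("data")
        .joinpath("gail")
        .joinpath(RAW_FILES[race])
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def oracle_log_rr(raw: dict, idx, ge50: bool) -> float:
    """Log relative risk, summed in sorted order (order-independence oracle)."""
    coef = raw["coefficients"]
    terms = [
        coef["age_at_menarche"][idx.menarche],
        coef["age_at_first_live_birth"][idx.first_birth],
        coef["n_biopsies"][idx.biopsies],
        coef["n_first_degree_relatives"][idx.relatives],
        coef["atypical_hyperplasia"][idx.hyperplasia],
        raw["interactions"]["first_birth_x_relatives"] * idx.first_birth * idx.relatives,
    ]
    if ge50:
        terms.append(raw["interactions"]["biopsies_age_ge50"] * idx.biopsies)
    return math.fsum(sorted(terms))


def oracle_relative_risk(raw: dict, idx, ge50: bool) -> float:
    return math.exp(oracle_log_rr(raw, idx, ge50))


def numeric_absolute_risk(
    raw: dict,
    idx,
    start: float,
    end: float,
    step: float = 0.005,
    competing_scale: float = 1.0,
) -> float:
    """Fine-grid midpoint integration of the cause-specific risk.

    P = integral over [start, end) of h1(t) * exp(-int_start^t (h1+h2)) dt
    with h1 the attributable-risk-adjusted, relative-risk-scaled breast
    cancer hazard and h2 the competing mortality hazard, both piecewise
    constant on the shipped 5-year bands.
    """
    start = max(float(start), 20.0)
    end = min(float(end), 90.0)
    if end <= start:
        return 0.0
    ts = np.arange(start, end - step / 2, step) + step / 2
    band = ((ts - 20.0) // 5.0).astype(int)
    lam1 = np.asarray(raw["baseline_hazard"], dtype=float)[band]
    lam2 = competing_scale * np.asarray(raw["competing_hazard"], dtype=float)[band]
    ge50 = ts >= 50.0
    rr = np.where(
        ge50, oracle_relative_risk(raw, idx, True), oracle_relative_risk(raw, idx, False)
    )
    oar = np.where(
        ge50, raw["one_minus_ar"]["ge_50"], raw["one_minus_ar"]["under_50"]
    )
    h1 = lam1 * oar * rr
    htot = h1 + lam2
    cum_to_mid = np.cumsum(htot) * step - htot * step / 2
    return float(np.sum(h1 * np.exp(-cum_to_mid) * step))
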