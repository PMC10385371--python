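"""Assay analysis and structure–activity bookkeeping.

Covers the potency stage of an enzyme-inhibition screen: Ellman-style
percent inhibition from absorbances, four-parameter logistic (4PL)
dose–response fitting for IC50, molecular-formula masses (monoisotopic
for HRMS "calcd." values, average for unit conversion), µM <-> µg/mL
conversion, fold potency against a reference inhibitor, substituent-
class SAR ordering by geometric-mean IC50, and the oral-bioavailability
Log P window flag (0 < Log P < 5, strict).

The 4PL model, in log10-concentration form with response increasing in
concentration:

    y(c) = bottom + (top - bottom) / (1 + 10^((log10 IC50 - log10 c) * hill))
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .cdft import rank_descriptor
from .elements import atomic_mass
from .io_formats import AssayTable, normalize_unit

#: proton mass, amu (for [M+H]+ reporting)
PROTON_MASS = 1.00728

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass
class DoseResponseFit:
    """A fitted 4PL dose–response curve."""

    compound_id: str
    bottom: float
    top: float
    hill: float
    log10_ic50: float
    ic50: float
    unit: str
    se_log10_ic50: float
    se_ic50: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return four_pl(np.asarray(conc, dtype=float), self.bottom, self.top,
                       self.hill, self.log10_ic50)


def four_pl(conc, bottom, top, hill, log10_ic50):
    """4PL response at the given concentrations (same unit as IC50)."""
    logc = np.log10(conc)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log10_ic50 - logc) * hill))


def percent_inhibition(a_control: float, a_sample: float,
                       a_blank: float = 0.0) -> float:
    """Percent inhibition from control/sample/blank absorbances."""
    if a_control <= a_blank:
        raise ValueError("control absorbance must exceed the blank")
    return 100.0 * ((a_control - a_blank) - (a_sample - a_blank)) / (
        a_control - a_blank
    )


def fit_ic50(
    assay: AssayTable | pd.DataFrame,
    compound_id: str,
    min_response_range: float = 20.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit of percent-inhibition vs concentration.

    Deterministic multistart: log-spaced IC50 guesses across the tested
    concentration range crossed with hill in {0.5, 1, 2}, plus a
    data-driven guess; best residual sum of squares wins.  Bounds:
    0 <= bottom <= top <= 110, 0.1 <= hill <= 10.
    """
    if isinstance(assay, AssayTable):
        sub = assay.for_compound(compound_id)
    else:
        sub = assay[assay["compound_id"] == compound_id]
        if sub.empty:
            raise KeyError(f"no assay rows for {compound_id!r}")
    units = sorted(set(normalize_unit(u) for u in sub["unit"]))
    if len(units) != 1:
        raise ValueError(f"mixed concentration units for {compound_id}: {units}")
    unit = units[0]
    conc = sub["concentration"].to_numpy(float)
    resp = sub["response"].to_numpy(float)
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations for a fit")
    mean_by_conc = pd.Series(resp).groupby(conc).mean()
    if mean_by_conc.max() - mean_by_conc.min() < min_response_range:
        raise ValueError(
            "no dose response: mean response range "
            f"{mean_by_conc.max() - mean_by_conc.min():.1f} < "
            f"{min_response_range} percentage points"
        )

    logc = np.log10(conc)
    lo, hi = logc.min(), logc.max()

    def residuals(p):
        return four_pl(conc, *p) - resp

    # data-driven start: concentration whose mean response is nearest
    # the half-way point
    half = (mean_by_conc.max() + mean_by_conc.min()) / 2.0
    c_half = mean_by_conc.index[np.argmin(np.abs(mean_by_conc - half))]
    starts = [(max(0.0, resp.min()), min(110.0, resp.max()), 1.0,
               np.log10(c_half))]
    for guess in np.linspace(lo, hi, 5):
        for hill0 in (0.5, 1.0, 2.0):
            starts.append((0.0, 100.0, hill0, guess))

    lower = [0.0, 0.0, 0.1, lo - 3.0]
    upper = [110.0, 110.0, 10.0, hi + 3.0]
    best = None
    for p0 in starts:
        p0 = np.clip(p0, lower, upper)
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper))
        except Exception:
            continue
        if not sol.success or sol.x[0] > sol.x[1]:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol)
    if best is None:
        return DoseResponseFit(compound_id, np.nan, np.nan, np.nan, np.nan,
                               np.nan, unit, np.nan, np.nan, np.nan,
                               converged=False, n_points=len(conc))
    rss, sol = best
    bottom, top, hill, log_ic50 = sol.x
    n, p = len(conc), 4
    se_log = np.nan
    if n > p:
        jtj = sol.jac.T @ sol.jac
        try:
            cov = np.linalg.inv(jtj) * rss / (n - p)
            se_log = float(np.sqrt(max(cov[3, 3], 0.0)))
        except np.linalg.LinAlgError:
            pass
    ic50 = float(10.0 ** log_ic50)
    se_ic50 = ic50 * np.log(10.0) * se_log if np.isfinite(se_log) else np.nan
    return DoseResponseFit(
        compound_id, float(bottom), float(top), float(hill), float(log_ic50),
        ic50, unit, se_log, se_ic50, rss, converged=True, n_points=n,
    )


# ---------------------------------------------------------------------------
# masses and units


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts."""
    formula = formula.strip()
    if not formula:
        raise ValueError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(
                f"unparseable token at position {pos} in {formula!r}"
            )
        pos = m.end()
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"unparseable token at position {pos} in {formula!r}")
    return counts


def formula_mass(formula: str, kind: str = "monoisotopic",
                 plus_proton: bool = False) -> float:
    """Molecular mass in amu: ``monoisotopic`` (most-abundant isotopes,
    the HRMS 'calcd.' convention) or ``average`` (standard atomic
    weights).  ``plus_proton`` adds one proton mass for [M+H]+."""
    mass = sum(
        n * atomic_mass(el, kind) for el, n in parse_formula(formula).items()
    )
    if plus_proton:
        mass += PROTON_MASS
    return mass


def convert_concentration(value: float, unit_in: str, unit_out: str,
                          mw: float | None = None) -> float:
    """Convert between µM and µg/mL; crossing molar/mass units needs a
    molecular weight (g/mol)."""
    unit_in = normalize_unit(unit_in)
    unit_out = normalize_unit(unit_out)
    if unit_in == unit_out:
        return value
    if mw is None or mw <= 0:
        raise ValueError("molecular weight required to convert µM <-> µg/mL")
    if unit_in == "µM" and unit_out == "µg/mL":
        return value * mw / 1000.0
    return value * 1000.0 / mw


def fold_potency(ic50_reference: float, ic50_test: float,
                 unit_reference: str | None = None,
                 unit_test: str | None = None) -> tuple[float, int]:
    """Potency of a test compound relative to the reference:
    ratio = IC50_ref / IC50_test (> 1 means the test compound is more
    potent).  Returns (ratio, nearest integer)."""
    if unit_reference is not None and unit_test is not None:
        if normalize_unit(unit_reference) != normalize_unit(unit_test):
            raise ValueError(
                f"unit mismatch: {unit_reference!r} vs {unit_test!r}"
            )
    if ic50_reference <= 0 or ic50_test <= 0:
        raise ValueError("IC50 values must be positive")
    ratio = ic50_reference / ic50_test
    return ratio, int(round(ratio))


def sar_rank_classes(rows: pd.DataFrame, tol: float = 0.0) -> str:
    """Order substituent classes by ascending geometric-mean IC50
    (most potent first); rendered like ``"Cl > H > OCH3"``.

    ``rows`` needs columns ``substituent_class`` and ``ic50``.
    """
    for col in ("substituent_class", "ic50"):
        if col not in rows.columns:
            raise ValueError(f"missing column {col!r}")
    if rows.empty or (rows.groupby("substituent_class").size() == 0).any():
        raise ValueError("every class needs at least one compound")
    if (rows["ic50"] <= 0).any():
        raise ValueError("IC50 values must be positive")
    gm = rows.groupby("substituent_class")["ic50"].apply(
        lambda v: float(np.exp(np.log(v).mean()))
    )
    return rank_descriptor(gm.to_dict(), direction="ascending", tol=tol)


def logp_window(logp: float) -> dict:
    """Oral-bioavailability heuristic: optimal iff 0 < Log P < 5
    (strict bounds)."""
    if not np.isfinite(logp):
        raise ValueError("Log P must be finite")
    in_window = 0.0 < logp < 5.0
    return {
        "logp": float(logp),
        "in_window": in_window,
        "verdict": "optimal" if in_window else "needs delivery-carrier note",
    }
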