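"""Percent-spliced-in (PSI) quantification and differential splicing
between cell groups.

PSI is the length-normalized inclusion fraction of an alternative-
splicing event:

    PSI = (I / lI) / (I / lI + E / lE)

with inclusion and exclusion junction counts I, E and effective junction
lengths lI, lE (for a skipped exon counted by junction reads: lI = 2,
lE = 1).  Events are pooled per group (pseudobulk) and compared with a
two-proportion chi-square score test on the raw junction counts — with
the effective lengths equal across groups, equality of the raw inclusion
proportion is equivalent to equality of PSI, and the raw-count test keeps
its nominal size.  P-values are Benjamini-Hochberg adjusted across
events.  ``skip_ratio = 1 - PSI`` is exposed for exon-skipping readouts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

EVENT_TYPES = ("SE", "A3SS", "A5SS", "RI", "MXE")


@dataclass
class SpliceEvent:
    event_id: str
    inclusion: int
    exclusion: int
    event_type: str = "SE"
    inclusion_length: int = 2
    exclusion_length: int = 1
    group: str = ""

    def __post_init__(self):
        if self.inclusion < 0 or self.exclusion < 0:
            raise ValueError("junction counts must be nonnegative")
        if self.inclusion_length <= 0 or self.exclusion_length <= 0:
            raise ValueError("effective lengths must be positive")


def compute_psi(event: SpliceEvent) -> float:
    """Length-normalized inclusion fraction; NaN when no reads at all."""
    inc = event.inclusion / event.inclusion_length
    exc = event.exclusion / event.exclusion_length
    if inc + exc == 0:
        return float("nan")
    return inc / (inc + exc)


def psi_from_counts(inclusion, exclusion, inclusion_length=2,
                    exclusion_length=1) -> np.ndarray:
    """Vectorized PSI over count arrays."""
    inc = np.asarray(inclusion, dtype=float) / inclusion_length
    exc = np.asarray(exclusion, dtype=float) / exclusion_length
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, inc / np.maximum(total, 1e-300), np.nan)


def skip_ratio(psi) -> np.ndarray:
    """Exon-skipping ratio, the PSI complement."""
    return 1.0 - np.asarray(psi, dtype=float)


def _pool(table: pd.DataFrame) -> pd.DataFrame:
    """Pseudobulk: sum I and E per event over cells/samples of a group."""
    pooled = table.groupby("event_id", sort=False).agg(
        type=("type", "first"), I=("I", "sum"), E=("E", "sum"),
        lI=("lI", "first"), lE=("lE", "first"))
    return pooled


def differential_psi(events_a: pd.DataFrame, events_b: pd.DataFrame,
                     label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
    """Per-event differential inclusion between two groups.

    Input tables carry columns ``event_id, type, I, E, lI, lE`` (extra
    rows per event are pooled).  Events absent from either group are
    excluded with a diagnostic column in ``attrs``.  Returns a frame with
    per-group PSI, ``delta_psi`` (B minus A), ``p`` and BH-adjusted ``q``.
    """
    a, b = _pool(events_a), _pool(events_b)
    shared = a.index.intersection(b.index)
    dropped = sorted(set(a.index).symmetric_difference(b.index))
    a, b = a.loc[shared], b.loc[shared]

    # effective lengths can vary per event; compute row-wise
    psi_a = psi_from_counts(a["I"].to_numpy(), a["E"].to_numpy(),
                            a["lI"].to_numpy(), a["lE"].to_numpy())
    psi_b = psi_from_counts(b["I"].to_numpy(), b["E"].to_numpy(),
                            b["lI"].to_numpy(), b["lE"].to_numpy())

    p = np.ones(len(shared))
    for i in range(len(shared)):
        tab = np.array([[a["I"].iloc[i], a["E"].iloc[i]],
                        [b["I"].iloc[i], b["E"].iloc[i]]], dtype=float)
        if tab.sum(axis=1).min() == 0 or tab.sum(axis=0).min() == 0:
            p[i] = 1.0
            continue
        p[i] = chi2_contingency(tab, correction=False)[1]
    q = multipletests(p, method="fdr_bh")[1] if len(p) else np.array([])

    result = pd.DataFrame({
        "type": a["type"].to_numpy(),
        f"psi_{label_a}": psi_a,
        f"psi_{label_b}": psi_b,
        "delta_psi": psi_b - psi_a,
        "p": p,
        "q": q,
    }, index=shared)
    result.attrs["dropped_events"] = dropped
    return result


def count_event_types(results: pd.DataFrame, q_threshold: float = 0.05,
                      dpsi_threshold: float = 0.1) -> pd.Series:
    """Tally significant events (q below and |delta PSI| at or above the
    thresholds) per event type."""
    sig = results[(results["q"] < q_threshold) &
                  (results["delta_psi"].abs() >= dpsi_threshold)]
    counts = sig["type"].value_counts()
    return pd.Series({t: int(counts.get(t, 0)) for t in EVENT_TYPES},
                     name="n_significant")
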