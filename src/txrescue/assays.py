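"""Derived-quantity computations for plate-based wet-lab readouts.

Mito-stress test: a Seahorse-style oxygen consumption rate (OCR) trace with
sequential injections — oligomycin (ATP-synthase inhibition), FCCP
(uncoupling), rotenone/antimycin A (complex I/III inhibition) — yields:

* NMOC (non-mitochondrial oxygen consumption) = min OCR after rot/AA,
* basal respiration = initial OCR - NMOC,
* ATP-linked OCR = initial OCR - min OCR after oligomycin,
* proton leak = min OCR after oligomycin - NMOC,
* coupling efficiency = ((basal + NMOC) - (leak + NMOC)) / (basal + NMOC).

"Initial OCR" is the mean over pre-injection cycles; post-injection
summaries use the phase minimum.  The coupling-efficiency formula is kept in
its additive written form; the NMOC terms cancel so it equals
(initial - min_oligomycin) / initial, i.e. ATP-linked OCR over total basal
oxygen consumption including the non-mitochondrial part.

Metabolic stoichiometry: glycolysis yields at most two lactate per glucose,
so a lactate/glucose ratio above 2 implies carbon sources other than the
consumed glucose; the excess-lactate fraction is max(0, 1 - 2/ratio).

Also here: ddCq percent-of-control with two reference genes, LDH release
fraction, per-protein signal normalization, and outlier screening
(Iglewicz–Hoaglin modified Z-score; iterative two-sided Grubbs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

PHASE_ORDER = ("basal", "post_oligomycin", "post_fccp", "post_rotenone_antimycin")
REQUIRED_PHASES = ("basal", "post_oligomycin", "post_rotenone_antimycin")


@dataclass
class MitoStressTrace:
    """Ordered OCR measurement cycles with injection-phase labels."""

    phases: list[str]
    ocr: np.ndarray  # pmol O2/min per normalized cell unit

    def __post_init__(self) -> None:
        self.ocr = np.asarray(self.ocr, dtype=float)
        if len(self.phases) != len(self.ocr):
            raise ValueError("one OCR value per cycle required")
        if np.any(self.ocr < 0):
            raise ValueError("OCR values must be non-negative")
        order = [PHASE_ORDER.index(p) for p in self.phases]  # raises on unknown
        if order != sorted(order):
            raise ValueError("phases out of injection order")
        for phase in REQUIRED_PHASES:
            if phase not in self.phases:
                raise ValueError(f"missing required phase: {phase!r}")

    def phase_values(self, phase: str) -> np.ndarray:
        return self.ocr[[i for i, p in enumerate(self.phases) if p == phase]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cycle": range(1, len(self.phases) + 1),
                             "phase": self.phases, "ocr": self.ocr})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MitoStressTrace":
        return cls(phases=df["phase"].tolist(), ocr=df["ocr"].to_numpy())


@dataclass
class MitoStressParams:
    nmoc: float
    basal_respiration: float
    atp_linked: float
    proton_leak: float
    coupling_efficiency: float
    leak_fraction_of_basal: float

    def to_dict(self) -> dict[str, float]:
        return {
            "nmoc": self.nmoc,
            "basal_respiration": self.basal_respiration,
            "atp_linked": self.atp_linked,
            "proton_leak": self.proton_leak,
            "coupling_efficiency": self.coupling_efficiency,
            "leak_fraction_of_basal": self.leak_fraction_of_basal,
        }


@dataclass
class MetabolicSummary:
    glucose_consumed: float
    lactate_produced: float
    lactate_glucose_ratio: float
    excess_lactate_fraction: float


@dataclass
class OutlierReport:
    values: np.ndarray
    scores: np.ndarray
    flagged: np.ndarray
    method: Literal["modified_z", "grubbs"]
    cutoff: float

    @property
    def flagged_values(self) -> np.ndarray:
        return self.values[self.flagged]


def mito_stress_params(trace: MitoStressTrace, as_printed: bool = False) -> MitoStressParams:
    """Extract respiration parameters from a mito-stress OCR trace.

    ``as_printed=True`` reproduces, for audit, a published formula set in
    which the ATP-linked formula is written identically to basal respiration
    (an evident transcription slip); the default uses the standard
    definition initial - min(post-oligomycin).
    """
    initial = float(trace.phase_values("basal").mean())
    min_oligo = float(trace.phase_values("post_oligomycin").min())
    min_rotaa = float(trace.phase_values("post_rotenone_antimycin").min())

    nmoc = min_rotaa
    basal = initial - min_rotaa
    proton_leak = min_oligo - min_rotaa
    atp_linked = basal if as_printed else initial - min_oligo
    denom = basal + nmoc
    if denom == 0:
        raise ValueError("coupling efficiency undefined: basal + NMOC = 0")
    coupling = ((basal + nmoc) - (proton_leak + nmoc)) / denom
    leak_fraction = proton_leak / basal if basal != 0 else float("nan")
    return MitoStressParams(
        nmoc=nmoc,
        basal_respiration=basal,
        atp_linked=atp_linked,
        proton_leak=proton_leak,
        coupling_efficiency=coupling,
        leak_fraction_of_basal=leak_fraction,
    )


def excess_lactate_fraction(
    glucose_consumed: float, lactate_produced: float
) -> MetabolicSummary:
    """Fraction of produced lactate that cannot derive from consumed glucose.

    With a maximum yield of 2 lactate per glucose, ratio = L/G and
    excess = max(0, 1 - 2/ratio); zero for any ratio <= 2.
    """
    if glucose_consumed <= 0:
        raise ValueError("glucose consumption must be positive")
    if lactate_produced < 0:
        raise ValueError("lactate production must be non-negative")
    ratio = lactate_produced / glucose_consumed
    excess = max(0.0, 1.0 - 2.0 / ratio) if ratio > 0 else 0.0
    return MetabolicSummary(
        glucose_consumed=glucose_consumed,
        lactate_produced=lactate_produced,
        lactate_glucose_ratio=ratio,
        excess_lactate_fraction=excess,
    )


def ddcq_percent_of_control(cq: pd.DataFrame, control_group: str = "control") -> pd.DataFrame:
    """Relative expression by the ddCq method, as percent of control.

    *cq* needs columns ``sample, group, cq_target, cq_ref1, cq_ref2``.
    dCq = Cq_target - mean(Cq_ref1, Cq_ref2); ddCq = dCq - mean dCq of the
    control group; percent = 100 * 2^(-ddCq), so the control-group geometric
    center sits at 100%.
    """
    required = {"sample", "group", "cq_target", "cq_ref1", "cq_ref2"}
    missing = required - set(cq.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    vals = cq[["cq_target", "cq_ref1", "cq_ref2"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("Cq values must be finite")
    out = cq.copy()
    out["dcq"] = out["cq_target"] - (out["cq_ref1"] + out["cq_ref2"]) / 2.0
    ctrl = out.loc[out["group"] == control_group, "dcq"]
    if ctrl.empty:
        raise ValueError(f"no samples in control group {control_group!r}")
    out["ddcq"] = out["dcq"] - ctrl.mean()
    out["percent_of_control"] = 100.0 * 2.0 ** (-out["ddcq"])
    return out


def ldh_release_fraction(medium_activity: float, lysate_activity: float) -> float:
    """LDH released to the medium as a fraction of total cellular LDH."""
    if medium_activity < 0 or lysate_activity < 0:
        raise ValueError("activities must be non-negative")
    total = medium_activity + lysate_activity
    if total == 0:
        raise ValueError("total LDH activity is zero")
    return medium_activity / total


def per_protein_normalize(
    signal: float | np.ndarray, protein_amount: float | np.ndarray
) -> float | np.ndarray:
    """Normalize a raw signal to the sample's total protein amount."""
    signal = np.asarray(signal, dtype=float)
    protein = np.asarray(protein_amount, dtype=float)
    if np.any(protein <= 0):
        raise ValueError("protein amount must be positive")
    out = signal / protein
    return float(out) if out.ndim == 0 else out


def _grubbs_critical(n: int, alpha: float) -> float:
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def detect_outliers(
    values: Sequence[float] | np.ndarray,
    method: Literal["modified_z", "grubbs"] = "modified_z",
    cutoff: float | None = None,
) -> OutlierReport:
    """Screen a sample for outliers.

    ``modified_z`` (Iglewicz–Hoaglin): M_i = 0.6745 (x_i - median) / MAD;
    values with |M_i| >= cutoff (default 3.5) are flagged; MAD = 0 yields no
    flags with a warning.  ``grubbs``: iterative two-sided Grubbs test at
    significance ``cutoff`` (default 0.05), removing one extreme at a time.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("outlier screening needs >= 3 values")

    if method == "modified_z":
        cut = 3.5 if cutoff is None else cutoff
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            warnings.warn("MAD is zero; no outliers flagged", stacklevel=2)
            scores = np.zeros_like(x)
            flagged = np.zeros(len(x), dtype=bool)
        else:
            scores = 0.6745 * (x - med) / mad
            flagged = np.abs(scores) >= cut
        return OutlierReport(values=x, scores=scores, flagged=flagged,
                             method="modified_z", cutoff=cut)

    if method == "grubbs":
        alpha = 0.05 if cutoff is None else cutoff
        flagged = np.zeros(len(x), dtype=bool)
        scores = np.zeros(len(x))
        active = np.arange(len(x))
        while len(active) >= 3:
            sub = x[active]
            sd = sub.std(ddof=1)
            if sd == 0:
                break
            g = np.abs(sub - sub.mean()) / sd
            imax = int(np.argmax(g))
            scores[active[imax]] = g[imax]
            if g[imax] > _grubbs_critical(len(sub), alpha):
                flagged[active[imax]] = True
                active = np.delete(active, imax)
            else:
                break
        return OutlierReport(values=x, scores=scores, flagged=flagged,
                             method="grubbs", cutoff=alpha)

    raise ValueError(f"unknown method: {method!r}")
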