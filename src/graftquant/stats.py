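"""Paired internal-control statistics for serial graft volumetry.

Each patient carries a treated graft on one side of the mandible and a
control graft contralaterally, measured at baseline and 6 months.  The
analysis computes, per patient, the volume change and percent change of
each side and the paired difference (treated change minus control
change), then the group summary: means, SDs, a paired two-sided t test,
and a paired Cohen's d.

Conventions (pinned, with both SD paths available):

* Descriptive SDs and Cohen's d use the population (n) denominator;
  the t statistic uses the sample (n-1) denominator, as a t test must.
* The group percent change is the mean of per-patient percents, not the
  percent of pooled volumes.
* Two intervals are reported for the mean paired difference: a
  ``dispersion interval (as published)`` equal to mean +/- 2 * SD_pop of
  the paired differences, and a conventional Student-t 95% CI,
  mean +/- t(0.975, n-1) * SD_sample / sqrt(n).  These differ by design
  and are labeled distinctly.
* Rounding (volumes to integers, percents to integer %, d to 2 decimals,
  p to 5 decimals) happens only in the presentation layer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .volio import MeasurementTable

__all__ = [
    "PairedRecord",
    "GroupSummary",
    "load_trial_table",
    "build_records",
    "summarize",
    "paired_t_test",
    "cohens_d_paired",
    "report",
]

log = logging.getLogger(__name__)


def sd_population(x) -> float:
    return float(np.std(np.asarray(x, float)))


def sd_sample(x) -> float:
    return float(np.std(np.asarray(x, float), ddof=1))


@dataclass
class PairedRecord:
    """One patient's four volumes (mm^3) and the derived paired quantities."""

    patient_id: str
    treated_side: str
    v0_treated: float
    v6_treated: float
    v0_control: float
    v6_control: float

    @property
    def change_treated(self) -> float:
        return self.v6_treated - self.v0_treated

    @property
    def change_control(self) -> float:
        return self.v6_control - self.v0_control

    @property
    def pct_treated(self) -> float:
        if self.v0_treated == 0:
            raise ZeroDivisionError(
                f"patient {self.patient_id}: percent change undefined, "
                "treated baseline volume is 0"
            )
        return 100.0 * self.change_treated / self.v0_treated

    @property
    def pct_control(self) -> float:
        if self.v0_control == 0:
            raise ZeroDivisionError(
                f"patient {self.patient_id}: percent change undefined, "
                "control baseline volume is 0"
            )
        return 100.0 * self.change_control / self.v0_control

    @property
    def paired_diff(self) -> float:
        """Treated change minus control change, mm^3."""
        return self.change_treated - self.change_control


@dataclass
class GroupSummary:
    n: int
    mean_v0_treated: float
    sd_v0_treated: float
    mean_v6_treated: float
    sd_v6_treated: float
    mean_v0_control: float
    sd_v0_control: float
    mean_v6_control: float
    sd_v6_control: float
    mean_change_treated: float
    sd_change_treated: float
    mean_change_control: float
    sd_change_control: float
    mean_pct_treated: float
    mean_pct_control: float
    mean_paired_diff: float
    sd_paired_diff: float              # population denominator
    sd_paired_diff_sample: float       # n-1 denominator
    t_statistic: float
    df: int
    p_value: float
    t_statistic_6mo: float
    p_value_6mo: float                  # paired t on the 6-month volumes
    cohens_d: float
    dispersion_interval: tuple          # mean +/- 2 SD_pop (as published)
    t_confidence_interval: tuple        # mean +/- t(.975, df) SD_sample/sqrt(n)


def load_trial_table() -> MeasurementTable:
    """The trial's measured graft volumes, shipped as a package fixture."""
    with resources.files("graftquant.data").joinpath("table2_volumes.csv").open() as fh:
        return MeasurementTable(pd.read_csv(fh, dtype={"patient_id": str}))


def build_records(table: MeasurementTable) -> list:
    """One :class:`PairedRecord` per patient with all four volumes.

    Patients missing any of the four (patient, side, timepoint) volumes
    (e.g. a reoperated patient without 6-month imaging) are excluded with
    a logged reason.
    """
    records = []
    df = table.data
    for pid in table.patients():
        sub = df[df["patient_id"] == pid]
        treated = sub["treated_side"].iloc[0]
        control = "Sin" if treated == "Dx" else "Dx"
        vols = {}
        for side, tp in [(treated, "baseline"), (treated, "6mo"), (control, "baseline"), (control, "6mo")]:
            row = sub[(sub["side"] == side) & (sub["timepoint"] == tp)]
            if len(row) == 1:
                vols[(side, tp)] = float(row["volume_mm3"].iloc[0])
        if len(vols) < 4:
            missing = 4 - len(vols)
            log.warning(
                "patient %s excluded: %d of 4 volumes missing", pid, missing
            )
            continue
        records.append(
            PairedRecord(
                pid,
                treated,
                vols[(treated, "baseline")],
                vols[(treated, "6mo")],
                vols[(control, "baseline")],
                vols[(control, "6mo")],
            )
        )
    return records


def paired_t_test(diffs) -> tuple:
    """Two-sided paired t test on the differences.

    t = mean / (SD_sample / sqrt(n)); p from the Student t distribution
    with n-1 degrees of freedom.
    """
    d = np.asarray(diffs, float)
    n = d.size
    if n < 2:
        raise ValueError("paired t test needs n >= 2")
    sd = sd_sample(d)
    if sd == 0:
        raise ValueError("zero variance: t statistic undefined")
    t = float(np.mean(d) / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return t, n - 1, p


def cohens_d_paired(diffs) -> float:
    """Paired Cohen's d = mean(diffs) / SD_pop(diffs)."""
    d = np.asarray(diffs, float)
    if d.size < 2:
        raise ValueError("Cohen's d needs n >= 2")
    sd = sd_population(d)
    if sd == 0:
        raise ValueError("zero variance: Cohen's d undefined")
    return float(np.mean(d) / sd)


def summarize(records) -> GroupSummary:
    if len(records) < 2:
        raise ValueError("need at least 2 complete patients to summarize")
    v0t = [r.v0_treated for r in records]
    v6t = [r.v6_treated for r in records]
    v0c = [r.v0_control for r in records]
    v6c = [r.v6_control for r in records]
    ct = [r.change_treated for r in records]
    cc = [r.change_control for r in records]
    pt = [r.pct_treated for r in records]
    pc = [r.pct_control for r in records]
    d = np.array([r.paired_diff for r in records])
    n = len(records)

    def _try_t(x):
        try:
            return paired_t_test(x)
        except ValueError:
            log.warning("zero-variance differences: t statistic undefined")
            return float("nan"), n - 1, float("nan")

    t, df_, p = _try_t(d)
    d6 = np.array(v6t) - np.array(v6c)
    t6, _, p6 = _try_t(d6)
    mean_d = float(np.mean(d))
    sd_pop_d = sd_population(d)
    sd_samp_d = sd_sample(d)
    tcrit = float(sps.t.ppf(0.975, df_))
    return GroupSummary(
        n=n,
        mean_v0_treated=float(np.mean(v0t)), sd_v0_treated=sd_population(v0t),
        mean_v6_treated=float(np.mean(v6t)), sd_v6_treated=sd_population(v6t),
        mean_v0_control=float(np.mean(v0c)), sd_v0_control=sd_population(v0c),
        mean_v6_control=float(np.mean(v6c)), sd_v6_control=sd_population(v6c),
        mean_change_treated=float(np.mean(ct)), sd_change_treated=sd_population(ct),
        mean_change_control=float(np.mean(cc)), sd_change_control=sd_population(cc),
        mean_pct_treated=float(np.mean(pt)), mean_pct_control=float(np.mean(pc)),
        mean_paired_diff=mean_d,
        sd_paired_diff=sd_pop_d,
        sd_paired_diff_sample=sd_samp_d,
        t_statistic=t, df=df_, p_value=p,
        t_statistic_6mo=t6, p_value_6mo=p6,
        cohens_d=cohens_d_paired(d) if sd_pop_d > 0 else float("nan"),
        dispersion_interval=(mean_d - 2 * sd_pop_d, mean_d + 2 * sd_pop_d),
        t_confidence_interval=(
            mean_d - tcrit * sd_samp_d / math.sqrt(n),
            mean_d + tcrit * sd_samp_d / math.sqrt(n),
        ),
    )


def gaining_grafts(records) -> dict:
    """Summary of treated grafts that gained volume (change > 0)."""
    gains = [r.change_treated for r in records if r.change_treated > 0]
    ctrl = [r.change_control for r in records]
    return {
        "n_gaining": len(gains),
        "mean_gain_mm3": float(np.mean(gains)) if gains else float("nan"),
        "gain_range_mm3": (min(gains), max(gains)) if gains else (None, None),
        "control_range_mm3": (min(ctrl), max(ctrl)),
    }


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def report(summary: GroupSummary, records, fmt: str = "dict"):
    """Presentation-rounded rendering of the per-patient table and summary.

    Volumes round to integers (half away from zero), percents to integer
    percent, Cohen's d to 2 decimals, p values to 5 decimals.  ``fmt`` is
    ``dict`` (JSON-ready), ``csv`` (a DataFrame of the patient table) or
    ``text``.
    """
    if not records:
        raise ValueError("no records to report")
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "treated_side": r.treated_side,
                "baseline_treated_mm3": _round_half_away(r.v0_treated),
                "sixmo_treated_mm3": _round_half_away(r.v6_treated),
                "baseline_control_mm3": _round_half_away(r.v0_control),
                "sixmo_control_mm3": _round_half_away(r.v6_control),
                "change_treated_mm3": _round_half_away(r.change_treated),
                "change_treated_pct": _round_half_away(r.pct_treated),
                "change_control_mm3": _round_half_away(r.change_control),
                "change_control_pct": _round_half_away(r.pct_control),
                "paired_diff_mm3": _round_half_away(r.paired_diff),
            }
        )
    s = summary
    summ = {
        "n": s.n,
        "baseline_treated_mean_sd": [_round_half_away(s.mean_v0_treated), _round_half_away(s.sd_v0_treated)],
        "sixmo_treated_mean_sd": [_round_half_away(s.mean_v6_treated), _round_half_away(s.sd_v6_treated)],
        "baseline_control_mean_sd": [_round_half_away(s.mean_v0_control), _round_half_away(s.sd_v0_control)],
        "sixmo_control_mean_sd": [_round_half_away(s.mean_v6_control), _round_half_away(s.sd_v6_control)],
        "change_treated_mean_sd": [_round_half_away(s.mean_change_treated), _round_half_away(s.sd_change_treated)],
        "change_control_mean_sd": [_round_half_away(s.mean_change_control), _round_half_away(s.sd_change_control)],
        "pct_treated_mean": _round_half_away(s.mean_pct_treated),
        "pct_control_mean": _round_half_away(s.mean_pct_control),
        "paired_diff_mean_sd": [_round_half_away(s.mean_paired_diff), _round_half_away(s.sd_paired_diff)],
        "t": round(s.t_statistic, 2),
        "df": s.df,
        "p": float(f"{s.p_value:.5f}"),
        "p_6mo_volumes": float(f"{s.p_value_6mo:.5f}"),
        "cohens_d": round(s.cohens_d, 2),
        "dispersion_interval_as_published": [
            _round_half_away(s.dispersion_interval[0]),
            _round_half_away(s.dispersion_interval[1]),
        ],
        "t_confidence_interval_95": [
            _round_half_away(s.t_confidence_interval[0]),
            _round_half_away(s.t_confidence_interval[1]),
        ],
        "conventions": {
            "descriptive_sd": "population (n denominator)",
            "t_test_sd": "sample (n-1 denominator)",
            "cohens_d": "mean(paired diff) / SD_pop(paired diff)",
            "group_percent": "mean of per-patient percents",
            "dispersion_interval": "mean +/- 2 SD_pop of paired diffs (as published)",
        },
    }
    if fmt == "dict":
        return {"records": rows, "summary": summ}
    if fmt == "csv":
        return pd.DataFrame(rows)
    if fmt == "text":
        lines = [pd.DataFrame(rows).to_string(index=False), ""]
        for k, v in summ.items():
            if k != "conventions":
                lines.append(f"{k}: {v}")
        return "\n".join(lines)
    raise ValueError(f"unknown format {fmt!r}")
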