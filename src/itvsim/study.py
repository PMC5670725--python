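"""Study drivers: phantom motion-range sweep and clinical cohort summaries.

The phantom sweep reruns the full in-silico experiment — simulate the
phase-sorted 4DCT and a free-breathing helical scan of the moving sphere,
build MIP/AIP projections, delineate PTVs by all five strategies and score
them against the 10-phase gold standard — at each motion amplitude.  Because
a single helical scan's respiratory start phase is arbitrary, free-breathing
results are computed for several uniformly spaced start phases and reported
per phase and as their mean.

The clinical side recomputes cohort summary statistics (mean +/- SD of DSC
and PTV ratio per strategy, and the fraction of patients whose PTV ratio
falls inside a +/-10% acceptance window) from a packaged 17-patient table of
per-patient motion vector, gold-standard PTV volume and per-strategy
(R, DSC) pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .delineation import Strategy, run_strategy
from .metrics import compare_masks
from .phantom import (
    AcquisitionConfig,
    MotionTrajectory,
    PhantomSpec,
    ScanModel,
    simulate_free_breathing,
    simulate_phase_stack,
)
from .projection import build_aip, build_mip

#: Strategies compared against the gold standard, in reporting order.
COMPARED_STRATEGIES = (Strategy.FB, Strategy.FB_AUG, Strategy.AIP, Strategy.MIP)

_FIXTURE_NAME = "clinical_table.csv"
_FIXTURE_SHA256 = "47e2907d4029aebdcad205df285a4a0e364d1efb37f740c0cb94bc2063758a10"
_FIXTURE_COLUMNS = [
    "patient", "m_cm", "ptv_gs_cc",
    "r_fb", "dsc_fb", "r_fbaug", "dsc_fbaug",
    "r_aip", "dsc_aip", "r_mip", "dsc_mip",
]
_N_PATIENTS = 17
_COLUMN_KEY = {
    Strategy.FB: ("r_fb", "dsc_fb"),
    Strategy.FB_AUG: ("r_fbaug", "dsc_fbaug"),
    Strategy.AIP: ("r_aip", "dsc_aip"),
    Strategy.MIP: ("r_mip", "dsc_mip"),
}


# ---------------------------------------------------------------------------
# Phantom sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepConfig:
    """Conditions of the phantom experiment.

    Amplitudes are half peak-to-peak SI excursions (cm), so the motion
    *range* of a row is twice its amplitude.  ``n_fb_start_phases`` helical
    scans with uniformly spaced respiratory start phases are simulated per
    amplitude for the FB-based strategies.
    """

    amplitudes_cm: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    spacing_cm: tuple[float, float, float] = (0.1, 0.1, 0.125)
    target_radius_cm: float = 1.5
    period_s: float = 4.0
    samples_per_bin: int = 8
    n_fb_start_phases: int = 8
    relative_threshold: float = 0.5
    pad_cm: float = 1.5
    seed: int = 0


@dataclass
class FbSample:
    """Free-breathing result for one scan start phase."""

    start_phase: float
    ptv_cc: float
    r_ratio: float
    dsc: float


@dataclass
class SweepRow:
    """Results for one motion amplitude.

    ``r`` and ``dsc`` map strategy name to PTV ratio / Dice coefficient vs
    the gold standard; FB entries are means over the swept start phases,
    whose individual values sit in ``fb_samples`` (and, for the FB-augmented
    strategy, ``fb_aug_samples``).
    """

    amplitude_cm: float
    range_cm: float
    ptv_gs_cc: float
    ptv_cc: dict[str, float]
    r: dict[str, float]
    dsc: dict[str, float]
    fb_samples: list[FbSample] = field(default_factory=list)
    fb_aug_samples: list[FbSample] = field(default_factory=list)


@dataclass
class SweepResult:
    config: SweepConfig
    rows: list[SweepRow]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            rec = {
                "range_cm": row.range_cm,
                "amplitude_cm": row.amplitude_cm,
                "ptv_gs_cc": row.ptv_gs_cc,
            }
            for s in COMPARED_STRATEGIES:
                rec[f"r_{s.value.lower()}"] = row.r[s.value]
                rec[f"dsc_{s.value.lower()}"] = row.dsc[s.value]
                rec[f"ptv_{s.value.lower()}_cc"] = row.ptv_cc[s.value]
            recs.append(rec)
        return pd.DataFrame.from_records(recs)

    def to_json_dict(self) -> dict:
        return {"config": asdict(self.config), "rows": [asdict(r) for r in self.rows]}

    def save(self, out_dir: str | Path, stem: str = "sweep") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / f"{stem}.csv", index=False)
        (out / f"{stem}.json").write_text(json.dumps(self.to_json_dict(), indent=2))


def run_phantom_sweep(config: SweepConfig = SweepConfig()) -> SweepResult:
    """Run the full delineation-strategy comparison across motion amplitudes."""
    rows = []
    acq = AcquisitionConfig(samples_per_bin=config.samples_per_bin)
    for amp in config.amplitudes_cm:
        traj = MotionTrajectory(
            amplitude_si=amp, period=config.period_s, seed=config.seed
        )
        spec = PhantomSpec.for_motion(
            traj,
            target_radius=config.target_radius_cm,
            spacing=config.spacing_cm,
            pad_cm=config.pad_cm,
        )
        stack = simulate_phase_stack(spec, traj, acq)
        mip = build_mip(stack)
        aip = build_aip(stack)
        thr = config.relative_threshold

        gs_ptv = run_strategy(Strategy.GS, stack=stack, relative_threshold=thr)
        ptv_cc: dict[str, float] = {}
        r: dict[str, float] = {}
        dsc: dict[str, float] = {}
        for s in (Strategy.AIP, Strategy.MIP):
            res = compare_masks(
                gs_ptv,
                run_strategy(s, mip=mip, aip=aip, relative_threshold=thr),
            )
            ptv_cc[s.value], r[s.value], dsc[s.value] = res.v_x, res.r_ratio, res.dsc

        fb_samples, fb_aug_samples = [], []
        for k in range(config.n_fb_start_phases):
            phase = k / config.n_fb_start_phases
            fb_img = simulate_free_breathing(spec, traj, ScanModel(start_phase=phase))
            for s, bucket in ((Strategy.FB, fb_samples), (Strategy.FB_AUG, fb_aug_samples)):
                res = compare_masks(
                    gs_ptv,
                    run_strategy(s, stack=stack, fb_image=fb_img, relative_threshold=thr),
                )
                bucket.append(FbSample(phase, res.v_x, res.r_ratio, res.dsc))
        for s, bucket in ((Strategy.FB, fb_samples), (Strategy.FB_AUG, fb_aug_samples)):
            ptv_cc[s.value] = float(np.mean([b.ptv_cc for b in bucket]))
            r[s.value] = float(np.mean([b.r_ratio for b in bucket]))
            dsc[s.value] = float(np.mean([b.dsc for b in bucket]))

        rows.append(
            SweepRow(
                amplitude_cm=amp,
                range_cm=2.0 * amp,
                ptv_gs_cc=gs_ptv.volume_cc,
                ptv_cc=ptv_cc,
                r=r,
                dsc=dsc,
                fb_samples=fb_samples,
                fb_aug_samples=fb_aug_samples,
            )
        )
    return SweepResult(config=config, rows=rows)


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalRecord:
    """One patient: motion vector, gold-standard PTV volume and per-strategy
    PTV ratio / DSC against the gold standard."""

    patient_id: int
    m_cm: float
    ptv_gs_cc: float
    r: dict[Strategy, float]
    dsc: dict[Strategy, float]


def _fixture_path() -> Path:
    return Path(str(resources.files("itvsim").joinpath(f"data/{_FIXTURE_NAME}")))


def load_clinical_table(path: str | Path | None = None) -> list[ClinicalRecord]:
    """Load the 17-patient cohort table (packaged fixture by default).

    The packaged fixture is checksum-validated; any table is validated for
    row count and value ranges (positive volumes and ratios, DSC in [0, 1]).
    """
    if path is None:
        p = _fixture_path()
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != _FIXTURE_SHA256:
            raise ValueError(
                f"packaged clinical table failed checksum validation ({digest})"
            )
    else:
        p = Path(path)
    df = pd.read_csv(p)
    missing = [c for c in _FIXTURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if len(df) != _N_PATIENTS:
        raise ValueError(f"clinical table must have {_N_PATIENTS} rows, got {len(df)}")
    records = []
    for _, row in df.iterrows():
        if row.m_cm <= 0 or row.ptv_gs_cc <= 0:
            raise ValueError(f"patient {row.patient}: non-positive motion or volume")
        r_map, dsc_map = {}, {}
        for s, (rcol, dcol) in _COLUMN_KEY.items():
            if row[rcol] <= 0:
                raise ValueError(f"patient {row.patient}: PTV ratio {rcol} must be > 0")
            if not 0.0 <= row[dcol] <= 1.0:
                raise ValueError(f"patient {row.patient}: DSC {dcol} out of [0, 1]")
            r_map[s] = float(row[rcol])
            dsc_map[s] = float(row[dcol])
        records.append(
            ClinicalRecord(
                patient_id=int(row.patient),
                m_cm=float(row.m_cm),
                ptv_gs_cc=float(row.ptv_gs_cc),
                r=r_map,
                dsc=dsc_map,
            )
        )
    return records


@dataclass(frozen=True)
class ClinicalSummary:
    strategy: Strategy
    mean_dsc: float
    sd_dsc: float
    mean_r: float
    sd_r: float
    n: int


def summarize_clinical(
    records: list[ClinicalRecord], strategy: Strategy | str, *, ddof: int = 1
) -> ClinicalSummary:
    """Mean and standard deviation of DSC and PTV ratio over the cohort.

    ``ddof=1`` (sample SD) by default; pass ``ddof=0`` for the population
    convention.
    """
    if not records:
        raise ValueError("no clinical records to summarize")
    strategy = Strategy(strategy)
    dscs = np.array([rec.dsc[strategy] for rec in records])
    rs = np.array([rec.r[strategy] for rec in records])
    return ClinicalSummary(
        strategy=strategy,
        mean_dsc=float(dscs.mean()),
        sd_dsc=float(dscs.std(ddof=ddof)),
        mean_r=float(rs.mean()),
        sd_r=float(rs.std(ddof=ddof)),
        n=len(records),
    )


def acceptance_window(
    records: list[ClinicalRecord], strategy: Strategy | str, tol: float = 0.10
) -> int:
    """Percentage of patients whose PTV ratio lies within ``1 +/- tol``.

    Boundaries are inclusive; the result is rounded to the nearest integer
    percent.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got {tol}")
    strategy = Strategy(strategy)
    eps = 1e-9
    lo, hi = 1.0 - tol - eps, 1.0 + tol + eps
    inside = sum(1 for rec in records if lo <= rec.r[strategy] <= hi)
    return int(round(100.0 * inside / len(records)))


def clinical_report(
    records: list[ClinicalRecord], *, window_tol: float = 0.10, ddof: int = 1
) -> pd.DataFrame:
    """Per-strategy cohort summary table (means, SDs, window percentage)."""
    rows = []
    for s in COMPARED_STRATEGIES:
        summ = summarize_clinical(records, s, ddof=ddof)
        rows.append(
            {
                "strategy": s.value,
                "mean_dsc": summ.mean_dsc,
                "sd_dsc": summ.sd_dsc,
                "mean_r": summ.mean_r,
                "sd_r": summ.sd_r,
                "window_pct": acceptance_window(records, s, window_tol),
                "n": summ.n,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Plots (optional conveniences mirroring the study figures)
# ---------------------------------------------------------------------------

def plot_sweep(result: SweepResult, path: str | Path) -> None:
    """PTV volume vs motion range for every strategy (one panel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_frame()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(df.range_cm, df.ptv_gs_cc, "k-o", label="10-phase GS")
    for s in COMPARED_STRATEGIES:
        ax.plot(df.range_cm, df[f"ptv_{s.value.lower()}_cc"], "--s", label=s.value)
    ax.set_xlabel("target motion range (cm)")
    ax.set_ylabel("PTV volume (cc)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    """DSC vs motion vector per strategy (four panels)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True, sharey=True)
    for ax, s in zip(axes.ravel(), COMPARED_STRATEGIES):
        ax.scatter([r.m_cm for r in records], [r.dsc[s] for r in records], s=18)
        ax.axhline(0.700, color="r", ls=":", lw=1)
        ax.set_title(s.value)
        ax.set_ylim(0.3, 1.02)
    for ax in axes[-1]:
        ax.set_xlabel("motion vector M (cm)")
    for ax in axes[:, 0]:
        ax.set_ylabel("DSC vs gold standard")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
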