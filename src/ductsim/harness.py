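"""Seeded batch experiments: phase diagrams, progressions, invasion counts.

Every replicate is identified by (condition, replicate index); its seed is
derived deterministically from the sweep's base seed so any row of a results
table can be re-run exactly.  Results are tidy pandas DataFrames with one row
per (condition, replicate, checkpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import TissueBlueprint
from .morphology import (SEVERITY, classify, classify_replicates,
                         detect_invasion)
from .params import SimulationParams, events_to_interval, preset
from .sim import Simulation, replicate_seed


@dataclass(frozen=True)
class Condition:
    """One cell of a sweep grid."""

    apoptosis: float = 0.0
    n_events: int = 20              # mitotic events per 1000 MCS
    axis: str = "perpendicular"
    archetype: str = "circle"
    preset_name: str = "default"
    preferential: bool = False
    run_length: int = 1000
    protect_luminal_progeny: bool = False

    def label(self) -> str:
        return (f"{self.archetype}:{self.preset_name}:a={self.apoptosis:g}"
                f":m={self.n_events}:{self.axis}"
                + (":pref" if self.preferential else ""))

    def params(self, seed: int) -> SimulationParams:
        p = preset(self.preset_name)
        # luminal daughters are subject to the same crowding-gated apoptosis
        # as every other LEP unless the protected-progeny variant is requested
        protect = bool(self.protect_luminal_progeny)
        return p.replace(
            apoptosis_probability=self.apoptosis,
            mitosis_interval=events_to_interval(self.n_events),
            division_axis=self.axis,
            protect_luminal_progeny=protect,
            preferential_end_proliferation=self.preferential,
            run_length=self.run_length,
            seed=seed,
        )


def run_replicate(condition: Condition, seed: int,
                  checkpoints: tuple[int, ...] = (1000,),
                  blueprint: TissueBlueprint | None = None) -> list[dict]:
    """Run one replicate and classify it at each checkpoint MCS."""
    sim = Simulation(condition.params(seed), archetype=condition.archetype,
                     blueprint=blueprint)
    rows = []

    checkpoints = tuple(sorted(set(int(c) for c in checkpoints)))
    for cp in checkpoints:
        sim.run(cp - sim.mcs)
        snap = sim.snapshot()
        label = classify(snap)
        inv = detect_invasion(snap)
        rows.append(dict(
            condition=condition.label(), seed=seed, mcs=cp,
            verdict=label.verdict, lumen_count=label.lumen_count,
            lumen_area=label.lumen_area,
            luminal_lep=label.luminal_lep_count,
            necrotic=label.necrotic_count,
            spanning_bridge=label.spanning_bridge,
            cribriform_with_necrosis=label.cribriform_with_necrosis,
            invasion_end=inv.end, invasion_duct=inv.duct,
            breach_count=inv.breach_count,
            apoptosis=condition.apoptosis, n_events=condition.n_events,
            axis=condition.axis, archetype=condition.archetype,
            preset=condition.preset_name, preferential=condition.preferential,
        ))
    return rows


@dataclass
class SweepSpec:
    conditions: list[Condition] = field(default_factory=list)
    n_replicates: int = 20
    checkpoints: tuple[int, ...] = (1000,)
    base_seed: int = 0
    blueprint: TissueBlueprint | None = None


def run_sweep(spec: SweepSpec, progress=None) -> pd.DataFrame:
    """Run every (condition, replicate); a crashed replicate is logged as a
    row with verdict ``"error"`` and excluded from consensus, never imputed."""
    rows = []
    for ci, cond in enumerate(spec.conditions):
        for rep in range(spec.n_replicates):
            seed = replicate_seed(spec.base_seed, ci * 10_000 + rep)
            try:
                rows.extend(run_replicate(cond, seed, spec.checkpoints,
                                          spec.blueprint))
            except Exception as exc:  # noqa: BLE001 - logged, not imputed
                rows.append(dict(condition=cond.label(), seed=seed,
                                 mcs=-1, verdict="error", error=str(exc)))
            if progress is not None:
                progress(cond.label(), rep)
    return pd.DataFrame(rows)


def consensus_table(results: pd.DataFrame, mcs: int | None = None) -> pd.DataFrame:
    """Per-condition consensus verdict (80% modal rule) at one checkpoint."""
    df = results[results.verdict != "error"]
    if mcs is not None:
        df = df[df.mcs == mcs]
    rows = []
    for cond, grp in df.groupby("condition", sort=False):
        rows.append(dict(condition=cond,
                         consensus=classify_replicates(list(grp.verdict)),
                         n=len(grp)))
    return pd.DataFrame(rows)


# ------------------------------------------------------ reference experiments
def cribriform_fraction(n_events_levels=(20, 25, 30), n_replicates: int = 50,
                        base_seed: int = 0, apoptosis: float = 0.01,
                        checkpoint: int = 1000) -> pd.DataFrame:
    """Fraction of circular-duct replicates classified cribriform at the
    checkpoint, for the parallel division axis, per mitotic-events level."""
    conds = [Condition(apoptosis=apoptosis, n_events=ev, axis="parallel")
             for ev in n_events_levels]
    spec = SweepSpec(conditions=conds, n_replicates=n_replicates,
                     checkpoints=(checkpoint,), base_seed=base_seed)
    df = run_sweep(spec)
    df = df[df.verdict != "error"]
    out = []
    for ev, cond in zip(n_events_levels, conds):
        grp = df[(df.condition == cond.label()) & (df.mcs == checkpoint)]
        frac = float((grp.verdict == "cribriform").mean()) if len(grp) else np.nan
        out.append(dict(n_events=ev, fraction=frac, n=len(grp)))
    return pd.DataFrame(out)


def progression_course(condition: Condition, n_replicates: int = 20,
                       base_seed: int = 0, until: int = 1000,
                       every: int = 100) -> pd.DataFrame:
    """Verdict time series per replicate (checkpoints every ``every`` MCS)."""
    spec = SweepSpec(conditions=[replace(condition, run_length=until)],
                     n_replicates=n_replicates,
                     checkpoints=tuple(range(every, until + 1, every)),
                     base_seed=base_seed)
    return run_sweep(spec)


def follows_order(verdicts: list[str], order: tuple[str, ...]) -> bool:
    """Does the sequence pass through the given verdicts in order (other
    verdicts in between are permitted, reversals of the listed ones are not)?"""
    pos = 0
    for v in verdicts:
        if pos < len(order) and v == order[pos]:
            pos += 1
    return pos == len(order)


def invasion_count(results: pd.DataFrame, mcs: int) -> pd.DataFrame:
    """Per-condition fractions of replicates with end / duct invasion."""
    df = results[(results.verdict != "error") & (results.mcs == mcs)]
    rows = []
    for cond, grp in df.groupby("condition", sort=False):
        rows.append(dict(condition=cond,
                         end_fraction=float(grp.invasion_end.mean()),
                         duct_fraction=float(grp.invasion_duct.mean()),
                         n=len(grp)))
    return pd.DataFrame(rows)


def ratio_collapse(results: pd.DataFrame, mcs: int | None = None) -> pd.DataFrame:
    """Collapse a proliferation x apoptosis sweep onto the single ratio
    (mitotic events) / (apoptosis probability).

    Conditions sharing a ratio bin are pooled; zero-apoptosis conditions form
    the top (infinite-ratio) bin.  Returns one row per bin with the modal
    verdict and its severity grade, ordered by increasing ratio.
    """
    df = results[results.verdict != "error"].copy()
    if mcs is not None:
        df = df[df.mcs == mcs]
    ratio = np.where(df.apoptosis > 0, df.n_events / df.apoptosis.replace(0, np.nan),
                     np.inf)
    df["ratio"] = ratio
    rows = []
    for r, grp in df.groupby("ratio"):
        counts = grp.verdict.value_counts()
        modal = counts.index[0]
        rows.append(dict(ratio=float(r), modal_verdict=modal,
                         severity=SEVERITY.get(modal, np.nan), n=len(grp)))
    return pd.DataFrame(rows).sort_values("ratio").reset_index(drop=True)


def severity_is_monotone(collapse: pd.DataFrame) -> bool:
    """Is the modal severity nondecreasing with the proliferation/apoptosis
    ratio (micropapillary -> cribriform -> solid/comedo)?"""
    sev = collapse.severity.to_numpy(dtype=float)
    return bool(np.all(np.diff(sev) >= 0))
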