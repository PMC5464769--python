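"""End-to-end experiment orchestration and simple group contrasts.

``run_experiment`` simulates a two-genotype-style cohort (each animal one
seeded generator run), applies the enabled activity analyses, and writes
tidy TSVs plus a JSON manifest with per-file checksums.  Re-running with
the same configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .actogram import (chi_square_periodogram, mean_counts_per_bin,
                       relative_activity, summarize_circadian)
from .synth import (ActivitySimConfig, build_light_schedule,
                    concatenate_schedules, simulate_activity)

log = logging.getLogger("chronolume")

#: Genotype-style generator presets.  Calibration of a hypothetical
#: light-hypersensitive mutant against a wild-type-like control: the mutant
#: preset has complete light masking, a longer free-running active phase,
#: a positive phase angle of entrainment, stronger dark activation and
#: lower overall activity.
PRESETS: dict[str, dict] = {
    "wildtype-like": dict(masking_strength=0.5, alpha_dd_h=12.3,
                          psi_h=-0.49, dark_gain=1.0, base_rate=3.8),
    "mutant-like": dict(masking_strength=1.0, alpha_dd_h=14.8,
                        psi_h=0.36, dark_gain=2.0, base_rate=2.2),
}


@dataclass(frozen=True)
class AnimalSpec:
    animal_id: str
    preset: str = "wildtype-like"
    seed: int = 0


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: tuple[AnimalSpec, ...]
    protocol: tuple[tuple[str, float], ...] = (("LD12:12", 240.0),
                                               ("DD", 432.0))
    intensity_cdm2: float = 6.6
    analyses: tuple[str, ...] = ("periodogram", "entrainment", "masking")
    bin_seconds: float = 300.0

    def __post_init__(self):
        ids = [a.animal_id for a in self.cohort]
        if len(set(ids)) != len(ids):
            raise ValueError("animal ids must be unique")
        for a in self.cohort:
            if a.preset not in PRESETS:
                raise ValueError(f"unknown preset {a.preset!r}")
        unknown = set(self.analyses) - {"periodogram", "entrainment",
                                        "masking"}
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")


def default_cohort(n_per_group: int = 6, master_seed: int = 0
                   ) -> tuple[AnimalSpec, ...]:
    """n wildtype-like vs n mutant-like animals with seeds derived from a
    master seed (one independent stream per animal)."""
    ss = np.random.SeedSequence(master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(2 * n_per_group)]
    cohort = []
    for i in range(n_per_group):
        cohort.append(AnimalSpec(f"wt{i + 1:02d}", "wildtype-like", seeds[i]))
    for i in range(n_per_group):
        cohort.append(AnimalSpec(f"mut{i + 1:02d}", "mutant-like",
                                 seeds[n_per_group + i]))
    return tuple(cohort)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _analyze_animal(spec: AnimalSpec, config: ExperimentConfig,
                    out_dir: Path) -> tuple[dict, list[Path]]:
    schedule = concatenate_schedules([
        build_light_schedule(name, dur, config.intensity_cdm2)
        for name, dur in config.protocol])
    sim = ActivitySimConfig(seed=spec.seed, **PRESETS[spec.preset])
    trace = simulate_activity(sim, schedule, bin_seconds=config.bin_seconds)
    log.info("animal=%s preset=%s seed=%d simulated %d bins",
             spec.animal_id, spec.preset, spec.seed, trace.n_bins)

    n_ld_days = int(round(config.protocol[0][1] / 24.0)) \
        if config.protocol[0][0] == "LD12:12" else 0
    files: list[Path] = []
    row: dict = {"animal_id": spec.animal_id, "preset": spec.preset,
                 "seed": spec.seed}

    act_path = out_dir / f"{spec.animal_id}_activity.tsv"
    from .io import write_activity_tsv
    write_activity_tsv(trace, act_path)
    files.append(act_path)

    if "periodogram" in config.analyses:
        dd_start = int(round(n_ld_days * 24.0 / trace.bin_h))
        from .synth import ActivityTrace
        sub = (ActivityTrace(trace.counts[dd_start:], trace.bin_seconds,
                             trace.start_time_h + n_ld_days * 24.0)
               if dd_start else trace)
        pg = chi_square_periodogram(sub)
        pg_path = out_dir / f"{spec.animal_id}_periodogram.tsv"
        pd.DataFrame({"period_h": pg.periods_h, "qp": pg.qp,
                      "signif_line": pg.signif_line}).to_csv(
            pg_path, sep="\t", index=False)
        files.append(pg_path)
        row.update(qp_max=pg.qp_max, peak_period_h=pg.peak_period_h,
                   peak_significant=pg.peak_significant)
    if "entrainment" in config.analyses and n_ld_days >= 3:
        cs = summarize_circadian(trace, schedule, n_ld_days)
        row.update(tau_h=cs.tau_h, psi_h=cs.psi_h, alpha_h=cs.alpha_h,
                   rho_h=cs.rho_h, r_precision=cs.r_precision,
                   z_precision=(None if math.isinf(cs.z_precision)
                                else cs.z_precision))
    if "masking" in config.analyses and n_ld_days >= 1:
        baseline = mean_counts_per_bin(trace, (0.0, n_ld_days * 24.0))
        ld_sched = build_light_schedule("LD12:12", n_ld_days * 24.0,
                                        config.intensity_cdm2)
        from .synth import ActivityTrace
        ld_bins = int(round(n_ld_days * 24.0 / trace.bin_h))
        ld_trace = ActivityTrace(trace.counts[:ld_bins], trace.bin_seconds,
                                 trace.start_time_h)
        mask = relative_activity(ld_trace, ld_sched, baseline)
        row.update(light_rel_pct=mask.light_phase_pct,
                   dark_rel_pct=mask.dark_phase_pct)
    return row, files


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Simulate and analyze every animal in the cohort.

    Writes per-animal TSVs, a cohort ``summary.tsv``, and ``manifest.json``
    listing every output file with its SHA-256 checksum.  Per-animal
    failures are isolated and reported in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows, all_files, errors = [], [], {}
    for spec in config.cohort:
        try:
            row, files = _analyze_animal(spec, config, out)
            rows.append(row)
            all_files.extend(files)
        except Exception as exc:  # isolate per-animal failures
            log.error("animal=%s failed: %s", spec.animal_id, exc)
            errors[spec.animal_id] = f"{type(exc).__name__}: {exc}"

    summary = pd.DataFrame(rows)
    summary_path = out / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    all_files.append(summary_path)

    manifest = {
        "package": "chronolume",
        "version": __version__,
        "config": {
            "cohort": [dataclasses.asdict(a) for a in config.cohort],
            "protocol": [list(p) for p in config.protocol],
            "intensity_cdm2": config.intensity_cdm2,
            "analyses": list(config.analyses),
            "bin_seconds": config.bin_seconds,
        },
        "errors": errors,
        "files": {f.name: _sha256(f) for f in sorted(all_files)},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def manifest_hash(manifest: dict) -> str:
    """Canonical hash of a manifest (for determinism checks)."""
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Two-group contrasts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupContrast:
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    difference: float       # mean_a - mean_b
    t_stat: float
    p_value: float
    paired: bool
    flagged_degenerate: bool = False


def group_contrast(values_a, values_b, paired: bool = False) -> GroupContrast:
    """Two-group contrast: Welch t-test (unpaired) or paired t-test,
    two-sided.  Degenerate inputs (zero variance everywhere) are flagged."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if paired and a.size != b.size:
        raise ValueError("paired contrast requires equal group sizes")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sem_a = float(stats.sem(a)) if a.size > 1 else math.nan
    sem_b = float(stats.sem(b)) if b.size > 1 else math.nan
    diff = mean_a - mean_b
    if paired:
        d = a - b
        if np.all(d == d[0]) and d[0] == 0:
            return GroupContrast(mean_a, mean_b, sem_a, sem_b, 0.0,
                                 0.0, 1.0, True, flagged_degenerate=True)
        t, p = stats.ttest_rel(a, b)
    else:
        if a.var() == 0 and b.var() == 0:
            p = 1.0 if mean_a == mean_b else 0.0
            return GroupContrast(mean_a, mean_b, sem_a, sem_b, diff,
                                 math.nan, p, False, flagged_degenerate=True)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupContrast(mean_a, mean_b, sem_a, sem_b, diff,
                         float(t), float(p), paired)
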