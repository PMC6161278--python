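"""End-to-end study orchestration.

``run_study`` simulates the full bath-substitution study in miniature —
single-ion baths, mixed Na+/K+ baths, anion/cation substitution baths, and a
pore-dead mutant — then runs every analysis stage over the simulated cohorts:

1. steady-state extraction and per-group I-V curves
2. reversal potentials of the expressing groups in each bath
3. per-oocyte activation time constants (exponential fits at -120 mV)
4. relative open probability and the modified Boltzmann gating fit
5. permeability-ratio inference from the multi-bath reversal potentials
6. per-voltage significance tests against the water-injected control

All randomness derives from one seed; rerunning with the same seed
regenerates every output table byte-identically (tables carry no timestamps
and use fixed float formatting).
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    build_iv,
    estimate_reversal_potential,
    extract_steady_state,
    relative_open_probability,
)
from .fits import fit_activation_exponential, fit_boltzmann
from .ghk import GHKCondition, GHKConditionSet, solve_permeability_ratios
from .simulate import SimulationConfig, generate_cohort
from .stats import student_t_test
from .traceio import RunConfig, write_run_config

__all__ = ["StudyManifest", "run_study", "default_groups"]

FLOAT_FMT = "%.9g"


def default_groups() -> dict[str, dict]:
    """The demo study design: cohorts mirroring the bath-substitution flow.

    Group sizes are miniature (4-6 oocytes) to keep the demo desk-scale while
    preserving every contrast the analysis consumes.
    """
    return {
        "water_NaK_1_1_cAMP": dict(bath="NaK_1_1", injection="water", cnmp="8Br-cAMP", n=4),
        "cRNA_NaK_1_1_free": dict(bath="NaK_1_1", injection="cRNA", cnmp="none", n=4),
        "cRNA_NaK_1_1_cGMP": dict(bath="NaK_1_1", injection="cRNA", cnmp="8Br-cGMP", n=4),
        "cRNA_NaK_1_1_cAMP": dict(bath="NaK_1_1", injection="cRNA", cnmp="8Br-cAMP", n=6),
        "cRNA_NaK_1_4_cAMP": dict(bath="NaK_1_4", injection="cRNA", cnmp="8Br-cAMP", n=5),
        "cRNA_gluconate_cAMP": dict(bath="gluconate", injection="cRNA", cnmp="8Br-cAMP", n=6),
        "cRNA_NMDG_cAMP": dict(bath="NMDG", injection="cRNA", cnmp="8Br-cAMP", n=4),
        "mutant_NaK_1_1_cAMP": dict(bath="NaK_1_1", injection="mutant", cnmp="8Br-cAMP", n=4),
    }


@dataclass
class StudyManifest:
    config_hash: str
    seed: int
    group_seeds: dict[str, int]
    outputs: dict[str, str]
    version: str

    def write(self, path: Path) -> None:
        doc = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "group_seeds": self.group_seeds,
            "outputs": self.outputs,
            "version": self.version,
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def _log(msg: str, t0: float) -> None:
    print(f"[tevckit +{time.perf_counter() - t0:6.2f}s] {msg}", file=sys.stderr)


def _write(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FMT)


def run_study(
    config: RunConfig | None = None,
    out_dir: str | Path = "study_out",
    seed: int = 0,
    base_sim: SimulationConfig | None = None,
    plots: bool = False,
) -> StudyManifest:
    """Run the full synthetic study and write result tables + manifest.

    Any stage failure aborts with a stage-named diagnostic; tables written
    before the failure are preserved.
    """
    t0 = time.perf_counter()
    config = config or RunConfig()
    base_sim = base_sim or SimulationConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    cfg_path = out / "run_config.yaml"
    write_run_config(config, cfg_path)
    config_hash = hashlib.sha256(cfg_path.read_bytes()).hexdigest()[:16]
    outputs["run_config"] = cfg_path.name

    groups = config.groups or default_groups()
    stage = "simulate"
    try:
        cohorts: dict[str, list] = {}
        group_seeds: dict[str, int] = {}
        for gidx, (label, g) in enumerate(sorted(groups.items())):
            gseed = (seed * 1009 + gidx) % (2**31)
            group_seeds[label] = gseed
            cfg = replace(
                base_sim,
                external=config.baths[g["bath"]],
                internal=config.internal,
                injection=g["injection"],
                cnmp=g["cnmp"],
                n_oocytes=int(g["n"]),
                seed=gseed,
                env=config.env,
            )
            cohorts[label] = generate_cohort(cfg, config.protocol)
        _log(f"simulated {len(cohorts)} cohorts", t0)

        stage = "steady-state extraction"
        rows = []
        ivs = {}
        for label, traces in cohorts.items():
            meas = []
            for tr in traces:
                meas.extend(extract_steady_state(tr, config.steady_state_window_s))
            ivs[label] = build_iv(meas, label=label)
            rows.append(ivs[label].to_frame())
        iv_table = pd.concat(rows, ignore_index=True)
        _write(iv_table, out / "iv_curves.csv")
        outputs["iv_curves"] = "iv_curves.csv"
        _log("I-V curves written", t0)

        stage = "reversal potentials"
        rev_rows = []
        rev_by_bath = {}
        for label, g in sorted(groups.items()):
            if g["injection"] != "cRNA" or g["cnmp"] != "8Br-cAMP":
                continue
            est = estimate_reversal_potential(ivs[label])
            rev_by_bath[g["bath"]] = est
            rev_rows.append(
                dict(group=label, bath=g["bath"], e_rev_mV=est.e_rev_mV, method=est.method)
            )
        _write(pd.DataFrame(rev_rows), out / "reversal_potentials.csv")
        outputs["reversal_potentials"] = "reversal_potentials.csv"
        _log("reversal potentials written", t0)

        stage = "activation kinetics"
        tau_rows = []
        kin_group = "cRNA_NaK_1_1_cAMP"
        if kin_group in cohorts:
            for tr in cohorts[kin_group]:
                k = int(np.argmin(tr.step_voltages_mV))  # most hyperpolarized step
                mask = tr.time_s >= config.kinetics_offset_s
                fit = fit_activation_exponential(tr.time_s[mask], tr.currents_uA[k][mask], seed=seed)
                tau_rows.append(
                    dict(
                        oocyte_id=tr.oocyte_id,
                        step_mV=float(tr.step_voltages_mV[k]),
                        tau_s=fit.params.tau,
                        amplitude_uA=fit.params.amplitude,
                        steady_uA=fit.params.steady,
                        rmse_uA=fit.rmse,
                        non_identifiable=fit.non_identifiable,
                    )
                )
            tau_frame = pd.DataFrame(tau_rows)
            tau_frame.loc[len(tau_frame)] = dict(
                oocyte_id="cohort_mean",
                step_mV=tau_frame["step_mV"].iloc[0],
                tau_s=tau_frame["tau_s"].mean(),
                amplitude_uA=tau_frame["amplitude_uA"].mean(),
                steady_uA=tau_frame["steady_uA"].mean(),
                rmse_uA=tau_frame["rmse_uA"].mean(),
                non_identifiable=bool(tau_frame["non_identifiable"].any()),
            )
            _write(tau_frame, out / "tau_fits.csv")
            outputs["tau_fits"] = "tau_fits.csv"
            _log("activation kinetics written", t0)

        stage = "gating fit"
        if "NaK_1_1" in rev_by_bath and kin_group in ivs:
            po = relative_open_probability(ivs[kin_group], rev_by_bath["NaK_1_1"].e_rev_mV)
            v_arr = np.array([p[0] for p in po])
            p_arr = np.array([p[1] for p in po])
            bf = fit_boltzmann(v_arr, p_arr, env=config.env, seed=seed)
            boltz = pd.DataFrame(
                [
                    dict(
                        group=kin_group,
                        z_delta=bf.params.z_delta,
                        v_half_mV=bf.params.v_half,
                        p_max=bf.params.p_max,
                        p_min=bf.params.p_min,
                        z_delta_ci_lo=bf.ci["z_delta"][0],
                        z_delta_ci_hi=bf.ci["z_delta"][1],
                        v_half_ci_lo=bf.ci["v_half"][0],
                        v_half_ci_hi=bf.ci["v_half"][1],
                        rmse=bf.rmse,
                        ci_method=bf.ci_method,
                        non_identifiable=bf.non_identifiable,
                    )
                ]
            )
            _write(boltz, out / "boltzmann_fit.csv")
            outputs["boltzmann_fit"] = "boltzmann_fit.csv"
            _log("gating fit written", t0)

        stage = "permeability ratios"
        if len(rev_by_bath) >= 2:
            conditions = [
                GHKCondition(external=config.baths[b], e_rev_mV=est.e_rev_mV)
                for b, est in sorted(rev_by_bath.items())
            ]
            cond_set = GHKConditionSet(conditions, internal=config.internal, env=config.env)
            sol = solve_permeability_ratios(cond_set, free_ions=("Na", "Cl"))
            perm = pd.DataFrame(
                [
                    dict(
                        ion=ion,
                        ratio=sol.perms.get(ion),
                        se=sol.ratio_se().get(ion, 0.0),
                    )
                    for ion in ("K", "Na", "Cl")
                ]
            )
            _write(perm, out / "permeability_ratios.csv")
            outputs["permeability_ratios"] = "permeability_ratios.csv"
            _log("permeability ratios written", t0)

        stage = "group statistics"
        stat_rows = []
        contrasts = [
            ("water_NaK_1_1_cAMP", "cRNA_NaK_1_1_cAMP"),
            ("water_NaK_1_1_cAMP", "mutant_NaK_1_1_cAMP"),
        ]
        per_oocyte = {}
        for label, traces in cohorts.items():
            tbl = {}
            for tr in traces:
                for m in extract_steady_state(tr, config.steady_state_window_s):
                    tbl.setdefault(m.command_mV, []).append(m.steady_state_uA)
            per_oocyte[label] = tbl
        for ga, gb in contrasts:
            if ga not in per_oocyte or gb not in per_oocyte:
                continue
            for v in sorted(per_oocyte[ga], reverse=True):
                res = student_t_test(
                    np.array(per_oocyte[ga][v]),
                    np.array(per_oocyte[gb][v]),
                    labels=(ga, gb),
                    voltage_mV=v,
                )
                stat_rows.append(
                    dict(
                        group_a=ga,
                        group_b=gb,
                        voltage_mV=v,
                        t=res.statistic,
                        df=res.df,
                        p=res.p_value,
                        significant=res.significant,
                    )
                )
        _write(pd.DataFrame(stat_rows), out / "group_stats.csv")
        outputs["group_stats"] = "group_stats.csv"
        _log("group statistics written", t0)

        if plots:
            stage = "plots"
            _plot_ivs(ivs, out / "iv_curves.png")
            outputs["iv_plot"] = "iv_curves.png"
            _log("plots written", t0)
    except Exception as exc:
        raise RuntimeError(f"study stage {stage!r} failed: {exc}") from exc

    manifest = StudyManifest(
        config_hash=config_hash,
        seed=seed,
        group_seeds=group_seeds,
        outputs=outputs,
        version=__version__,
    )
    manifest.write(out / "manifest.json")
    _log("manifest written; study complete", t0)
    return manifest


def _plot_ivs(ivs: dict, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, iv in sorted(ivs.items()):
        ax.errorbar(iv.voltages_mV, iv.mean_uA, yerr=iv.sd_uA, label=label, marker="o", ms=3)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("V (mV)")
    ax.set_ylabel("I (uA)")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
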