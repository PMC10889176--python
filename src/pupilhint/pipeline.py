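"""End-to-end orchestration: simulate -> preprocess -> epoch -> analyze -> report.

Every stage is deterministic given the master seed; each result file
carries the configuration hash in a leading ``#`` comment line so runs
are attributable to their exact parameter set.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import epochs as ep
from . import io as pio
from . import preprocess as pp
from . import stats as st
from .config import PipelineConfig
from .hint import StaircaseConfig, outcome_from_responses
from .synth import StudyDesign, default_listeners, default_pupil_params, gen_session

log = logging.getLogger(__name__)


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.9g")


def simulate(cfg: PipelineConfig, outdir) -> Path:
    """Generate the default-design dataset (8 subjects, 10 conditions)."""
    design = StudyDesign(n_subjects=cfg.n_subjects,
                         sentences_per_list=cfg.n_sentences)
    sc = StaircaseConfig(
        n_sentences=cfg.n_sentences, start_snr=cfg.start_snr,
        speech_level=cfg.speech_level, step=cfg.step,
        noise_lead=cfg.noise_lead, noise_tail=cfg.noise_tail,
        sentence_duration=cfg.sentence_duration, outcome_rule=cfg.outcome_rule)
    listeners = default_listeners(design, np.random.SeedSequence([cfg.seed, 17]))
    params = default_pupil_params(design)
    return gen_session(design, listeners, params, cfg.seed, outdir, cfg=sc)


def preprocess_dataset(dataset_dir, cfg: PipelineConfig):
    """Clean every recording and epoch it; yield per-condition results.

    Returns (curves, long_rows): the per subject x condition mean curves
    and the long-table rows of (snr outcome, PPD).
    """
    dataset_dir = Path(dataset_dir)
    with open(dataset_dir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    curves: list[ep.ConditionCurve] = []
    rows = []
    for subject in sorted(manifest["events"]):
        events = pio.read_events(dataset_dir / manifest["events"][subject])
        responses = pio.read_responses(dataset_dir / manifest["responses"][subject])
        for key, rel in sorted(manifest["samples"].items()):
            subj, mic, config = key.split("|")
            if subj != subject:
                continue
            rec = pio.read_pupil_csv(dataset_dir / rel, subject_id=subj,
                                     microphone=mic, configuration=config,
                                     unit=manifest.get("unit", "au"))
            ev = events[(events["microphone"] == mic)
                        & (events["configuration"] == config)]
            trace = pp.preprocess_recording(
                rec, ev, fs=cfg.fs, confidence_floor=cfg.confidence_floor,
                k_mad=cfg.k_mad, pre_margin=cfg.pre_margin,
                post_margin=cfg.post_margin, z=cfg.outlier_z,
                min_len=cfg.min_island, islands=cfg.outlier_islands,
                max_gap=cfg.max_gap, window=cfg.smooth_window,
                interpolate=cfg.interpolate)
            eps = ep.epoch_trace(
                trace, ev, fs=cfg.fs, start=cfg.epoch_start, end=cfg.epoch_end,
                max_removed=cfg.max_removed_fraction)
            if not eps:
                log.warning("%s %s/%s: every trial excluded; condition dropped",
                            subj, mic, config)
                continue
            curve = ep.average_epochs(eps, subj, mic, config)
            ppd = ep.peak_pupil_dilation(
                curve, (cfg.ppd_window_start, cfg.ppd_window_end)).ppd
            resp = responses[(responses["microphone"] == mic)
                             & (responses["configuration"] == config)]
            outcome = outcome_from_responses(resp, cfg.outcome_rule)
            curves.append(curve)
            rows.append((subj, mic, config, outcome, ppd, curve.n_epochs_used))
    long_table = pd.DataFrame(rows, columns=list(pio.LONG_COLUMNS))
    return curves, long_table


def analyze(dataset_dir, cfg: PipelineConfig, outdir) -> dict:
    """Run the full analysis battery and write result tables.

    Produces the long table, one-way and two-way repeated-measures
    ANOVAs for SNR and PPD, Shapiro-Wilk residual checks, Games-Howell
    post hoc tables per factor, the Bonferroni threshold, the Spearman
    SNR~PPD correlation and the condition mean curves.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves, long_table = preprocess_dataset(dataset_dir, cfg)
    _write_csv(long_table, outdir / "long_table.csv", cfg)

    noise = long_table[long_table["configuration"] != "S0"]
    results: dict = {"long_table": long_table, "curves": curves,
                     "anova": {}, "shapiro": {}, "games_howell": {},
                     "config_hash": cfg.config_hash}
    for response in ("snr_db", "ppd_au"):
        for factor in ("configuration", "microphone"):
            try:
                tab, resid = st.rm_anova_oneway(noise, response, factor)
            except ValueError as exc:
                log.warning("one-way ANOVA %s~%s skipped: %s", response, factor, exc)
                continue
            results["anova"][f"oneway_{response}_{factor}"] = tab
            results["shapiro"][f"oneway_{response}_{factor}"] = st.shapiro_wilk(resid)
            _write_csv(tab, outdir / f"anova_oneway_{response}_{factor}.csv", cfg)
        try:
            tab2, resid2 = st.rm_anova_twoway_interaction(noise, response)
        except ValueError as exc:
            log.warning("two-way ANOVA for %s skipped: %s", response, exc)
        else:
            results["anova"][f"twoway_{response}"] = tab2
            results["shapiro"][f"twoway_{response}"] = st.shapiro_wilk(resid2)
            _write_csv(tab2, outdir / f"anova_twoway_{response}.csv", cfg)
        for factor in ("configuration", "microphone"):
            levels = sorted(noise[factor].unique())
            groups = [noise.loc[noise[factor] == lv, response].to_numpy()
                      for lv in levels]
            gh = st.games_howell(groups)
            gh.insert(0, "level_j", [levels[j] for j in gh.pop("group_j")])
            gh.insert(0, "level_i", [levels[i] for i in gh.pop("group_i")])
            results["games_howell"][f"{response}_{factor}"] = gh
            _write_csv(gh, outdir / f"gameshowell_{response}_{factor}.csv", cfg)

    m = len(results["games_howell"].get("snr_db_configuration", ())) or 1
    results["bonferroni_alpha"] = st.bonferroni_threshold(cfg.alpha, m)
    rho, pval = st.spearman(noise["snr_db"], noise["ppd_au"])
    results["spearman"] = (rho, pval)
    _write_csv(pd.DataFrame({"rho": [rho], "p": [pval], "n": [len(noise)]}),
               outdir / "correlation.csv", cfg)

    curve_rows = []
    for c in curves:
        curve_rows.append(pd.DataFrame({
            "subject": c.subject_id, "microphone": c.microphone,
            "configuration": c.configuration, "rel_time": c.rel_time,
            "mean": c.mean, "sd": c.sd, "n": c.n_per_point,
        }))
    _write_csv(pd.concat(curve_rows, ignore_index=True),
               outdir / "curves.csv", cfg)
    report(results, outdir / "report.txt", cfg)
    return results


def report(results: dict, path, cfg: PipelineConfig) -> str:
    """Human-readable summary mirroring the study's table layouts."""
    lt = results["long_table"]
    noise = lt[lt["configuration"] != "S0"]
    lines = [f"# pupilhint analysis report (config_hash={cfg.config_hash})", ""]
    lines.append("== Condition summary: SNR (dB) and PPD (au), mean (SD) ==")
    for factor in ("configuration", "microphone"):
        lines.append(f"-- by {factor} --")
        g = noise.groupby(factor)
        for level, sub in g:
            lines.append(
                f"  {level:<12} SNR {sub['snr_db'].mean():+6.2f} "
                f"({sub['snr_db'].std(ddof=1):5.2f})   "
                f"PPD {sub['ppd_au'].mean():.4f} ({sub['ppd_au'].std(ddof=1):.4f})")
    lines.append("")
    lines.append("== Repeated-measures ANOVA ==")
    for name, tab in results["anova"].items():
        lines.append(f"-- {name} --")
        for r in tab.itertuples():
            lines.append(f"  {r.term:<26} df=({r.num_df},{r.den_df}) "
                         f"F={r.F:9.4f}  p={r.p:.4f}")
        w, p = results["shapiro"][name]
        lines.append(f"  residual normality (Shapiro-Wilk): W={w:.4f} p={p:.4f}")
    lines.append("")
    rho, pval = results["spearman"]
    lines.append(f"== Spearman SNR ~ PPD: rho={rho:.3f}, p={pval:.3f} ==")
    lines.append(f"Bonferroni-adjusted alpha: {results['bonferroni_alpha']:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def run_end_to_end(cfg: PipelineConfig, workdir) -> dict:
    """simulate + analyze in one call; returns the analyze() results."""
    workdir = Path(workdir)
    dataset = simulate(cfg, workdir / "dataset")
    return analyze(dataset, cfg, workdir / "results")
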