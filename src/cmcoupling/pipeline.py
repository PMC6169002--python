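"""End-to-end study orchestration.

:func:`run_full_study` drives simulate -> preprocess -> segment -> estimate
(per-trial MI and bidirectional TE) -> statistics for every tone-burst-count
(NTB) condition, mirroring a repeated-measures design: the same simulated
subjects are observed under every NTB level, before and after stimulation.
Per-subject latent coupling gains are drawn once and reused across
conditions so the within-subject correlation structure that the
repeated-measures ANOVA assumes is actually present in the data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .infotheory import mi_ksg
from .preprocess import preprocess_recording, segment_trials
from .protocols import EmbeddingSpec, FilterSpec, StimProtocol, SynthConfig
from .stats import (
    AnovaResult,
    pearson_corr,
    rm_anova,
    summarize_conditions,
    surrogate_test,
)
from .synthetic import gen_cmc_recording
from .transfer_entropy import ragwitz_optimize, scan_prediction_time, te_ksg

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "AnalysisReport", "run_full_study", "write_estimates",
           "read_estimates"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated study.

    The NTB levels, inter-trial interval and pulse parameters follow the
    stimulation protocol; estimator settings (k = 4 neighbors, prediction
    times scanned over 10-49 ms) follow the analysis defaults. ``u_scan``
    switches between scanning the prediction-time grid per direction (slow,
    thorough) and using the fixed ``embedding.u``. ``ragwitz`` switches
    between per-subject Ragwitz optimization of (d, tau) and the fixed
    ``embedding`` values.
    """

    ntb_levels: tuple[int, ...] = (100, 150, 200, 250, 300)
    n_subjects: int = 9
    synth: SynthConfig = field(default_factory=SynthConfig)
    filters: FilterSpec = field(default_factory=FilterSpec)
    embedding: EmbeddingSpec = field(default_factory=lambda: EmbeddingSpec(
        d=2, tau=2, u=25.0, k=4, theiler=20))
    window_pre: float = 1.0
    window_post: float = 1.0
    u_scan: bool = False
    u_grid_ms: tuple[float, ...] = tuple(float(u) for u in range(10, 50))
    ragwitz: bool = False
    n_surrogates: int = 0
    subject_sd: float = 0.15
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ntb_levels"] = list(self.ntb_levels)
        d["u_grid_ms"] = list(self.u_grid_ms)
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Aggregated results of one study run.

    ``estimates`` is the long-format per-trial table (columns: subject, ntb,
    phase, direction, trial, value_nats, p_surrogate, lfp_amp, emg_amp);
    every reported statistic below is recomputable from it.
    """

    estimates: pd.DataFrame
    summary: pd.DataFrame
    anova_pre_post: dict[tuple[str, int], AnovaResult]
    anova_direction: dict[tuple[str, int], AnovaResult]
    anova_ntb: dict[str, AnovaResult]
    correlations: pd.DataFrame
    config: RunConfig

    def to_text(self) -> str:
        """Human-readable summary (means +/- SD to 4 decimals, ANOVA tables,
        correlation table)."""
        lines = [
            "Cortico-muscular coupling analysis report",
            f"config hash: {self.config.config_hash}   seed: {self.config.seed}",
            "",
            "Per-condition estimates (mean ± SD across subjects):",
        ]
        for (direction, ntb, phase), row in self.summary.iterrows():
            lines.append(
                f"  {direction:>4s}  NTB={ntb:<4d} {phase:<5s} "
                f"{row['mean']:.4f} ± {row['sd']:.4f}  (n={int(row['n'])})"
            )
        lines.append("")
        lines.append("Pre vs post rANOVA (per direction and NTB):")
        for (direction, ntb), res in sorted(self.anova_pre_post.items()):
            mark = "*" if res.significant else " "
            lines.append(
                f"  {direction:>4s}  NTB={ntb:<4d} "
                f"F({res.df_condition},{res.df_error})={res.F:.3f} "
                f"p={res.p_value:.4f}{mark}"
            )
        lines.append("")
        lines.append("Descending vs ascending TE rANOVA (post-stimulation):")
        for (phase, ntb), res in sorted(self.anova_direction.items()):
            mark = "*" if res.significant else " "
            lines.append(
                f"  {phase:>5s} NTB={ntb:<4d} "
                f"F({res.df_condition},{res.df_error})={res.F:.3f} "
                f"p={res.p_value:.4f}{mark}"
            )
        lines.append("")
        lines.append("Across-NTB rANOVA (post-stimulation):")
        for direction, res in sorted(self.anova_ntb.items()):
            mark = "*" if res.significant else " "
            lines.append(
                f"  {direction:>4s}  "
                f"F({res.df_condition},{res.df_error})={res.F:.3f} "
                f"p={res.p_value:.4f}{mark}"
            )
        lines.append("")
        lines.append("Amplitude-coupling Pearson correlations (post, pooled trials):")
        for _, row in self.correlations.iterrows():
            mark = "*" if row["p_value"] < 0.05 else " "
            lines.append(
                f"  NTB={int(row['ntb']):<4d} {row['amplitude']:>7s} vs "
                f"{row['measure']:>4s}: rho²={row['rho_squared']:.4f} "
                f"p={row['p_value']:.4f}{mark}"
            )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_estimates(self.estimates, out / "estimates.csv")
        self.summary.to_csv(out / "summary.csv")
        self.correlations.to_csv(out / "correlations.csv", index=False)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh)
        with open(out / "report.txt", "w") as fh:
            fh.write(self.to_text() + "\n")


def write_estimates(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _condition_seed(base_seed: int, subject: int, ntb: int) -> int:
    """Deterministic per-(subject, condition) generator seed below 2^31."""
    ss = np.random.SeedSequence([base_seed, subject, ntb])
    return int(ss.generate_state(1)[0] % (2**31))


def run_full_study(config: RunConfig) -> AnalysisReport:
    """Run the full simulated study and return its report.

    For each subject and NTB level a pre-stimulation and a post-stimulation
    recording are generated (the post recording with the NTB-scaled coupling
    gain), preprocessed and cut into trials; per trial the MI between the
    LFP and rectified EMG and the TE in both directions are estimated.
    Repeated-measures ANOVAs compare pre vs post, descending vs ascending,
    and the five NTB levels; Pearson correlations relate per-trial signal
    amplitudes to the coupling measures.
    """
    cfg = config
    master = np.random.default_rng(cfg.seed)
    subj_mult = np.exp(master.normal(0.0, cfg.subject_sd, cfg.n_subjects))

    rows = []
    for subject in range(cfg.n_subjects):
        subject_spec: dict[str, EmbeddingSpec] = {}
        for ntb in cfg.ntb_levels:
            stage = f"subject {subject}, NTB {ntb}"
            try:
                protocol = StimProtocol(ntb=ntb)
                scfg = replace(
                    cfg.synth,
                    coupling_desc=cfg.synth.coupling_desc * subj_mult[subject],
                    coupling_asc=cfg.synth.coupling_asc * subj_mult[subject],
                    seed=_condition_seed(cfg.seed, subject, ntb),
                )
                for phase in ("pre", "post"):
                    rec = gen_cmc_recording(protocol, scfg, phase=phase)
                    prep = preprocess_recording(rec, cfg.filters)
                    pre_ts, post_ts = segment_trials(
                        prep, cfg.window_pre, cfg.window_post, protocol
                    )
                    trials = pre_ts if phase == "pre" else post_ts
                    if cfg.ragwitz and phase not in subject_spec:
                        d_l, tau_l = ragwitz_optimize(
                            trials.lfp[0], k=cfg.embedding.k)
                        subject_spec[phase] = replace(
                            cfg.embedding, d=d_l, tau=tau_l)
                    spec = subject_spec.get(phase, cfg.embedding)
                    rows.extend(
                        _estimate_trials(
                            trials, spec, cfg, subject, ntb, phase)
                    )
            except Exception as err:
                raise RuntimeError(f"pipeline stage failed at {stage}") from err

    estimates = pd.DataFrame(rows)
    return _build_report(estimates, cfg)


def _estimate_trials(trials, spec, cfg: RunConfig, subject, ntb, phase):
    fs = trials.fs
    out = []
    for t, (lfp, emg) in enumerate(trials):
        lfp_amp = float(np.mean(np.abs(lfp)))
        emg_amp = float(np.mean(emg))  # EMG is rectified, already >= 0
        mi = mi_ksg(lfp, emg, k=spec.k, theiler=spec.theiler)
        if cfg.u_scan:
            best_u, _ = scan_prediction_time(
                lfp, emg, spec, u_grid_ms=cfg.u_grid_ms, fs=fs)
            spec_desc = replace(spec, u=best_u)
            best_u_asc, _ = scan_prediction_time(
                emg, lfp, spec, u_grid_ms=cfg.u_grid_ms, fs=fs)
            spec_asc = replace(spec, u=best_u_asc)
        else:
            spec_desc = spec_asc = spec
        if cfg.n_surrogates > 0:
            seed = _condition_seed(cfg.seed + 7, subject * 1000 + t, ntb)
            desc = surrogate_test(
                lfp, emg, spec_desc, n_surrogates=cfg.n_surrogates,
                fs=fs, seed=seed)
            asc = surrogate_test(
                emg, lfp, spec_asc, n_surrogates=cfg.n_surrogates,
                fs=fs, seed=seed + 1)
        else:
            desc = te_ksg(lfp, emg, spec_desc, fs=fs)
            asc = te_ksg(emg, lfp, spec_asc, fs=fs)
        common = dict(subject=subject, ntb=ntb, phase=phase, trial=t,
                      lfp_amp=lfp_amp, emg_amp=emg_amp)
        out.append({**common, "direction": "mi", "value_nats": mi.value,
                    "p_surrogate": np.nan})
        out.append({**common, "direction": "desc", "value_nats": desc.value,
                    "p_surrogate": desc.p_value if desc.p_value is not None
                    else np.nan})
        out.append({**common, "direction": "asc", "value_nats": asc.value,
                    "p_surrogate": asc.p_value if asc.p_value is not None
                    else np.nan})
    return out


def _build_report(estimates: pd.DataFrame, cfg: RunConfig) -> AnalysisReport:
    # subject-level cell means feed the ANOVAs; trials pool for correlations
    cell = (
        estimates.groupby(["direction", "ntb", "phase", "subject"])
        ["value_nats"].mean().reset_index()
    )

    summary_in = estimates.copy()
    summary_in["condition"] = list(zip(
        summary_in["direction"], summary_in["ntb"], summary_in["phase"]))
    subj_means = (
        estimates.groupby(["direction", "ntb", "phase", "subject"])
        ["value_nats"].mean().reset_index()
    )
    subj_means["condition"] = list(zip(
        subj_means["direction"], subj_means["ntb"], subj_means["phase"]))
    summary = summarize_conditions(
        subj_means, value="value_nats", condition="condition")
    summary.index = pd.MultiIndex.from_tuples(
        summary.index, names=["direction", "ntb", "phase"])

    anova_pre_post: dict[tuple[str, int], AnovaResult] = {}
    for direction in ("mi", "desc", "asc"):
        for ntb in cfg.ntb_levels:
            sub = cell[(cell.direction == direction) & (cell.ntb == ntb)]
            anova_pre_post[(direction, ntb)] = rm_anova(
                sub, value="value_nats", subject="subject", condition="phase")

    anova_direction: dict[tuple[str, int], AnovaResult] = {}
    for phase in ("pre", "post"):
        for ntb in cfg.ntb_levels:
            sub = cell[(cell.direction.isin(["desc", "asc"]))
                       & (cell.ntb == ntb) & (cell.phase == phase)]
            anova_direction[(phase, ntb)] = rm_anova(
                sub, value="value_nats", subject="subject",
                condition="direction")

    anova_ntb: dict[str, AnovaResult] = {}
    if len(cfg.ntb_levels) >= 2:
        for direction in ("mi", "desc", "asc"):
            sub = cell[(cell.direction == direction) & (cell.phase == "post")]
            anova_ntb[direction] = rm_anova(
                sub, value="value_nats", subject="subject", condition="ntb")

    corr_rows = []
    post = estimates[estimates.phase == "post"]
    for ntb in cfg.ntb_levels:
        for direction in ("mi", "desc", "asc"):
            sub = post[(post.direction == direction) & (post.ntb == ntb)]
            for amp_col, amp_name in (("lfp_amp", "lfp"), ("emg_amp", "emg")):
                try:
                    res = pearson_corr(
                        sub[amp_col].to_numpy(), sub["value_nats"].to_numpy())
                except ValueError:
                    continue
                corr_rows.append({
                    "ntb": ntb, "amplitude": amp_name, "measure": direction,
                    "rho": res.rho, "rho_squared": res.rho_squared,
                    "p_value": res.p_value, "n": res.n,
                })
    correlations = pd.DataFrame(corr_rows)

    return AnalysisReport(
        estimates=estimates, summary=summary,
        anova_pre_post=anova_pre_post, anova_direction=anova_direction,
        anova_ntb=anova_ntb, correlations=correlations, config=cfg,
    )
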