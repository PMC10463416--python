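"""Study orchestration: simulate -> preprocess -> power/PAF/coherence -> stats.

``run_study`` drives the whole analysis from a single :class:`StudyConfig`
with deterministic seeding, per-subject isolation (no subject's stage output
depends on another subject until the statistics stage), TSV outputs and a
JSON manifest recording per-subject cleaning counts (components removed,
channels interpolated, trials remaining).

Also provides the external I/O surface: a minimal 16-bit EDF writer, EDF
reading through mne, sidecar event tables and montage TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .core import BANDS, Epochs, Montage, Recording
from .synthetic_eeg import (
    ArtifactSpec,
    CouplingSpec,
    OscSpec,
    SynthConfig,
    generate_group_cohort,
)
from .preprocess import (
    AllChannelsBadError,
    check_inclusion,
    filter_chain,
    make_epochs,
    ocular_ica,
    reject_and_repair,
    rereference,
)
from .spectral import band_power, compute_log_spectrum, task_specific_power
from .paf import adjust_one_over_f, estimate_paf
from .coherence import frontoparietal_ispc, surface_laplacian, task_specific_coherence
from .stats import (
    compare_correlations,
    fdr_bh,
    mixed_anova,
    paired_ttest,
    pearson,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "run_study",
    "process_subject",
    "read_recording",
    "write_recording",
    "write_events_tsv",
    "read_events_tsv",
    "save_epochs",
    "load_epochs",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyConfig:
    """Everything one study run needs; validates before any computation."""

    seed: int = 0
    n_con: int = 16
    n_nf1: int = 16
    synth: SynthConfig = field(default_factory=SynthConfig)
    do_ica: bool = True
    rest_threshold_uv: float = 200.0
    task_threshold_uv: float = 120.0
    min_epochs: int = 15
    power_window_ms: tuple[float, float] = (900.0, 1900.0)
    power_resolution_hz: float = 1.0
    paf_resolution_hz: float = 0.25
    do_coherence: bool = True
    ica_max_iter: int = 200

    def validate(self) -> None:
        self.synth.validate()
        if self.n_con < 1 or self.n_nf1 < 1:
            raise ValueError("need at least one subject per group")
        if min(self.rest_threshold_uv, self.task_threshold_uv) <= 0:
            raise ValueError("rejection thresholds must be positive")
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be >= 1")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if isinstance(synth, dict):
            synth = dict(synth)
            bands = {
                name: OscSpec(**spec) if isinstance(spec, dict) else spec
                for name, spec in synth.pop("bands", {}).items()
            }
            coupling = tuple(
                CouplingSpec(**c) if isinstance(c, dict) else c
                for c in synth.pop("coupling", ())
            )
            artifacts = synth.pop("artifacts", None)
            if isinstance(artifacts, dict):
                artifacts = ArtifactSpec(**artifacts)
            kwargs = dict(synth)
            if bands:
                kwargs["bands"] = bands
            if coupling:
                kwargs["coupling"] = coupling
            if artifacts is not None:
                kwargs["artifacts"] = artifacts
            if "blocks" in kwargs:
                kwargs["blocks"] = tuple(kwargs["blocks"])
            synth = SynthConfig(**kwargs)
        for key in ("power_window_ms",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(synth=synth, **d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# Per-subject processing
# --------------------------------------------------------------------------


@dataclass
class SubjectOutput:
    subject_id: str
    group: str
    age_years: float
    counts: dict
    rest_included: bool
    task_included: bool
    rest_rows: list          # band power rows
    paf_rows: list
    task_rows: list
    coherence_rows: list
    error: str | None = None


def process_subject(
    subject_id: str,
    group: str,
    age: float,
    rec: Recording,
    cfg: StudyConfig,
    ica_seed: int = 0,
) -> SubjectOutput:
    """Run the full single-subject pipeline on one continuous recording."""
    counts: dict = {"components_removed": 0, "channels_interpolated": 0}
    rest_rows: list = []
    paf_rows: list = []
    task_rows: list = []
    coh_rows: list = []
    montage = rec.montage

    has_rest = any(code in ("rest_open", "rest_closed") for _, code in rec.events)
    has_task = any(code.startswith("stim_") for _, code in rec.events)

    rec = rereference(rec, "averaged-mastoids")

    rest_included = task_included = False
    rest_clean = None

    if has_rest:
        filt = filter_chain(rec, "rest")
        ep = make_epochs(filt, "rest-arbitrary")
        if cfg.do_ica:
            model, ep = ocular_ica(ep, seed=ica_seed, max_iter=cfg.ica_max_iter)
            counts["components_removed"] += len(model.flagged)
        ep = reject_and_repair(ep, cfg.rest_threshold_uv)
        counts["channels_interpolated"] += len(ep.bad_channels)
        ep = rereference(ep, "common-average")
        report = check_inclusion(ep, "rest", cfg.min_epochs)
        counts["rest_trials_remaining"] = report.counts
        rest_included = report.included
        rest_clean = ep

        if rest_included:
            band_by_cond = {}
            for cond in ("eyes_open", "eyes_closed"):
                spec = compute_log_spectrum(
                    ep, cfg.power_window_ms, cfg.power_resolution_hz, condition=cond
                )
                bp = band_power(spec, "all_scalp", montage=montage)
                band_by_cond[cond] = bp
                for band, value in bp.values.items():
                    rest_rows.append(
                        {
                            "subject": subject_id,
                            "group": group,
                            "condition": cond,
                            "channel_set": "all_scalp",
                            "band": band,
                            "log_power": value,
                        }
                    )
                pspec = compute_log_spectrum(
                    ep, (0.0, 1900.0), cfg.paf_resolution_hz, condition=cond
                )
                est = estimate_paf(adjust_one_over_f(pspec))
                paf_rows.append(
                    {
                        "subject": subject_id,
                        "group": group,
                        "condition": cond,
                        "paf_hz": est.paf_hz,
                        "flag": est.flag,
                        "override_applied": est.override_applied,
                    }
                )

    if has_task:
        filt = filter_chain(rec, "task")
        ep = make_epochs(filt, "task")
        if cfg.do_ica:
            model, ep = ocular_ica(ep, seed=ica_seed + 1, max_iter=cfg.ica_max_iter)
            counts["components_removed"] += len(model.flagged)
        ep = reject_and_repair(ep, cfg.task_threshold_uv)
        counts["channels_interpolated"] += len(ep.bad_channels)
        ep = rereference(ep, "common-average")
        report = check_inclusion(ep, "task", cfg.min_epochs)
        counts["task_trials_remaining"] = report.counts
        task_included = report.included and rest_included

        if task_included:
            rest_open_bp = band_power(
                compute_log_spectrum(
                    rest_clean, cfg.power_window_ms, cfg.power_resolution_hz, condition="eyes_open"
                ),
                "all_scalp",
                montage=montage,
            )
            rest_open_mf = band_power(
                compute_log_spectrum(
                    rest_clean, cfg.power_window_ms, cfg.power_resolution_hz, condition="eyes_open"
                ),
                "mid_frontal",
            )
            for load in ("1back", "2back"):
                spec = compute_log_spectrum(
                    ep,
                    cfg.power_window_ms,
                    cfg.power_resolution_hz,
                    condition=load,
                    correct_only=True,
                )
                for chset, baseline in (
                    ("all_scalp", rest_open_bp),
                    ("mid_frontal", rest_open_mf),
                ):
                    bp = band_power(spec, chset, montage=montage)
                    adj = task_specific_power(bp, baseline)
                    for band in bp.values:
                        task_rows.append(
                            {
                                "subject": subject_id,
                                "group": group,
                                "load": load,
                                "channel_set": chset,
                                "band": band,
                                "log_power": bp.values[band],
                                "adjusted_log_power": adj.values[band],
                            }
                        )

            if cfg.do_coherence:
                lap_task = surface_laplacian(ep)
                lap_rest = surface_laplacian(rest_clean)
                rest_est = frontoparietal_ispc(lap_rest, "rest")
                for load in ("1back", "2back"):
                    ests = frontoparietal_ispc(lap_task, load)
                    for pair, est in ests.items():
                        adj = task_specific_coherence(est, rest_est[pair])
                        coh_rows.append(
                            {
                                "subject": subject_id,
                                "group": group,
                                "region_pair": pair,
                                "load": load,
                                "ispc_raw": adj.ispc,
                                "ispc_rest": adj.rest_ispc,
                                "ispc_adjusted": adj.adjusted,
                                "n_trials": adj.n_trials,
                            }
                        )

    return SubjectOutput(
        subject_id=subject_id,
        group=group,
        age_years=age,
        counts=counts,
        rest_included=rest_included,
        task_included=task_included,
        rest_rows=rest_rows,
        paf_rows=paf_rows,
        task_rows=task_rows,
        coherence_rows=coh_rows,
    )


# --------------------------------------------------------------------------
# Study-level statistics
# --------------------------------------------------------------------------


def _safe_anova(anova_rows, measure, sub, within):
    """Run one mixed ANOVA, skipping measures with a degenerate error stratum
    (possible on tiny or constant-valued cohorts)."""
    try:
        tab = mixed_anova(sub, "value", "subject", within=within)
    except ValueError as err:
        logger.warning("ANOVA for %s skipped: %s", measure, err)
        return
    for _, row in tab.iterrows():
        anova_rows.append({"measure": measure, **row.to_dict()})


def _rest_statistics(rest: pd.DataFrame, paf: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    anova_rows, t_rows = [], []
    for band in BANDS:
        sub = rest[rest["band"] == band].rename(columns={"log_power": "value"})
        if sub.empty:
            continue
        _safe_anova(anova_rows, band, sub, ("condition",))
        nf1 = sub[sub["group"] == "NF1"].pivot(
            index="subject", columns="condition", values="value"
        )
        if len(nf1) >= 2:
            res = paired_ttest((nf1["eyes_closed"] - nf1["eyes_open"]).to_numpy())
            t_rows.append(
                {
                    "measure": band,
                    "contrast": "eyes_closed - eyes_open (NF1)",
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "d": res.d,
                    "n": res.n,
                }
            )
    if not paf.empty:
        sub = paf.rename(columns={"paf_hz": "value"})
        _safe_anova(anova_rows, "paf", sub, ("condition",))
    return pd.DataFrame(anova_rows), pd.DataFrame(t_rows)


def _task_statistics(task: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chset, bands in (("all_scalp", list(BANDS)), ("mid_frontal", ["theta"])):
        for band in bands:
            sub = task[(task["band"] == band) & (task["channel_set"] == chset)]
            if sub.empty:
                continue
            sub = sub.rename(columns={"adjusted_log_power": "value"})
            measure = band if chset == "all_scalp" else f"mid_frontal_{band}"
            _safe_anova(rows, measure, sub, ("load",))
    return pd.DataFrame(rows)


def _coherence_statistics(coh: pd.DataFrame) -> pd.DataFrame:
    if coh.empty:
        return pd.DataFrame()
    sub = coh.rename(columns={"ispc_adjusted": "value"})
    rows: list = []
    _safe_anova(rows, "theta_ispc_adjusted", sub, ("region_pair", "load"))
    return pd.DataFrame(rows)


def _correlation_statistics(
    rest: pd.DataFrame, paf: pd.DataFrame, subjects: pd.DataFrame
) -> pd.DataFrame:
    """Per-group age correlations for delta/theta power and PAF, with the
    Fisher r-to-z group comparison and BH-FDR over the five comparisons."""
    age = subjects.set_index("subject")["age_years"]
    measures = []
    for band in ("delta", "theta"):
        for cond in ("eyes_open", "eyes_closed"):
            sub = rest[(rest["band"] == band) & (rest["condition"] == cond)]
            if sub.empty:
                continue
            measures.append(
                (f"{band}_{cond}", sub.set_index("subject")[["group", "log_power"]])
            )
    if not paf.empty:
        mean_paf = paf.groupby(["subject"]).agg(
            group=("group", "first"), log_power=("paf_hz", "mean")
        )
        measures.append(("paf_open_closed_mean", mean_paf))

    rows = []
    for name, table in measures:
        row = {"measure": name}
        stats_by_group = {}
        for grp in ("CON", "NF1"):
            vals = table[table["group"] == grp]["log_power"]
            common = vals.index.intersection(age.index)
            if len(common) < 4:
                stats_by_group = None
                break
            r, p = pearson(age.loc[common], vals.loc[common])
            row[f"r_{grp.lower()}"] = r
            row[f"p_{grp.lower()}"] = p
            stats_by_group[grp] = (r, len(common))
        if not stats_by_group:
            continue
        (r1, n1), (r2, n2) = stats_by_group["CON"], stats_by_group["NF1"]
        cmp = compare_correlations(r1, n1, r2, n2)
        row.update({"z": cmp.z, "p_compare": cmp.p})
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        flags, q = fdr_bh(out["p_compare"].to_numpy())
        out["q_compare"] = q
        out["fdr_significant"] = flags
    return out


# --------------------------------------------------------------------------
# Study runner
# --------------------------------------------------------------------------


@dataclass
class StudyResult:
    subjects: pd.DataFrame
    rest_power: pd.DataFrame
    paf: pd.DataFrame
    task_power: pd.DataFrame
    coherence: pd.DataFrame
    anova_rest: pd.DataFrame
    ttests_rest: pd.DataFrame
    anova_task: pd.DataFrame
    anova_coherence: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            name: getattr(self, name)
            for name in (
                "subjects",
                "rest_power",
                "paf",
                "task_power",
                "coherence",
                "anova_rest",
                "ttests_rest",
                "anova_task",
                "anova_coherence",
                "correlations",
            )
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6f")
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def run_study(cfg: StudyConfig, out_dir=None) -> StudyResult:
    """Simulate the cohort and run every analysis stage plus statistics.

    Identical config + seed reproduces identical outputs.  Subjects failing
    an inclusion rule are dropped from the corresponding analyses only, and
    a subject whose cleaning fails outright (all channels bad) is excluded
    with the reason recorded in the manifest.
    """
    cfg.validate()
    cohort = generate_group_cohort(cfg.synth, cfg.n_con, cfg.n_nf1, seed=cfg.seed)
    ica_rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(97,)))

    outputs: list[SubjectOutput] = []
    for subj in cohort:
        ica_seed = int(ica_rng.integers(0, 2**31 - 1))
        try:
            out = process_subject(
                subj.subject_id, subj.group, subj.age_years, subj.recording, cfg, ica_seed
            )
        except AllChannelsBadError as err:
            logger.warning("subject %s excluded: %s", subj.subject_id, err)
            out = SubjectOutput(
                subj.subject_id,
                subj.group,
                subj.age_years,
                counts={},
                rest_included=False,
                task_included=False,
                rest_rows=[],
                paf_rows=[],
                task_rows=[],
                coherence_rows=[],
                error=str(err),
            )
        outputs.append(out)

    subjects = pd.DataFrame(
        {
            "subject": o.subject_id,
            "group": o.group,
            "age_years": o.age_years,
            "rest_included": o.rest_included,
            "task_included": o.task_included,
        }
        for o in outputs
    )
    rest = pd.DataFrame([r for o in outputs for r in o.rest_rows])
    paf = pd.DataFrame([r for o in outputs for r in o.paf_rows])
    task = pd.DataFrame([r for o in outputs for r in o.task_rows])
    coh = pd.DataFrame([r for o in outputs for r in o.coherence_rows])

    anova_rest, ttests = (
        _rest_statistics(rest, paf) if not rest.empty else (pd.DataFrame(), pd.DataFrame())
    )
    anova_task = _task_statistics(task) if not task.empty else pd.DataFrame()
    anova_coh = _coherence_statistics(coh)
    correlations = (
        _correlation_statistics(rest, paf, subjects) if not rest.empty else pd.DataFrame()
    )

    manifest = {
        "package_version": _pkg_version,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "n_con": cfg.n_con,
        "n_nf1": cfg.n_nf1,
        "subjects": {
            o.subject_id: {
                "group": o.group,
                "rest_included": o.rest_included,
                "task_included": o.task_included,
                "error": o.error,
                **o.counts,
            }
            for o in outputs
        },
    }
    result = StudyResult(
        subjects=subjects,
        rest_power=rest,
        paf=paf,
        task_power=task,
        coherence=coh,
        anova_rest=anova_rest,
        ttests_rest=ttests,
        anova_task=anova_task,
        anova_coherence=anova_coh,
        correlations=correlations,
        manifest=manifest,
    )
    if out_dir is not None:
        result.write(out_dir)
    return result


# --------------------------------------------------------------------------
# EDF + sidecar I/O
# --------------------------------------------------------------------------


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_recording(rec: Recording, path, events_path=None, montage_path=None) -> None:
    """Write a recording as 16-bit EDF plus sidecar event/montage TSVs.

    Record duration is 1 s; the final partial record is zero-padded and the
    true sample count is stored in the event sidecar header so reading can
    trim the padding.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))
    n_ch = rec.montage.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))

    data = np.zeros((n_ch, n_rec * spr))
    data[:, : rec.n_samples] = rec.data
    # Physical bounds quantized to what the 8-char header fields store, so
    # the scaling a reader reconstructs matches the one used to digitize.
    pmin = np.floor(data.min(axis=1) * 100.0) / 100.0
    pmax = np.ceil(data.max(axis=1) * 100.0) / 100.0
    flat = pmax - pmin < 1e-12
    pmin[flat] -= 1.0
    pmax[flat] += 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (n_ch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(n_ch), 4))
        for lab in rec.montage.labels:
            fh.write(_pad(lab, 16))
        for _ in range(n_ch):
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_pad("uV", 8))
        for v in pmin:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for v in pmax:
            fh.write(_pad(f"{v:.2f}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmin), 8))
        for _ in range(n_ch):
            fh.write(_pad(str(dmax), 8))
        for _ in range(n_ch):
            fh.write(_pad("HP:0Hz", 80))
        for _ in range(n_ch):
            fh.write(_pad(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_pad("", 32))
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())

    if events_path is not None:
        write_events_tsv(rec, events_path)
    if montage_path is not None:
        rec.montage.to_tsv(montage_path)


def write_events_tsv(rec: Recording, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# rate={rec.rate:g} n_samples={rec.n_samples}\n")
        fh.write("sample\tseconds\tcode\n")
        for sample, code in sorted(rec.events):
            fh.write(f"{sample}\t{sample / rec.rate:.6f}\t{code}\n")


def read_events_tsv(path) -> tuple[list[tuple[int, str]], dict]:
    events, meta = [], {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for item in line[1:].split():
                    if "=" in item:
                        k, v = item.split("=", 1)
                        meta[k] = float(v) if "." in v or "e" in v else int(v)
                continue
            if line.startswith("sample"):
                continue
            sample, _, code = line.split("\t")
            events.append((int(sample), code))
    return events, meta


def read_recording(path, events_path=None, montage_path=None) -> Recording:
    """Read an EDF/BDF file (via mne) into a Recording in microvolts.

    Channel labels must map onto the sidecar montage when one is given;
    otherwise the standard montage is used and unmapped labels are an error.
    Event sample indices outside the recording are rejected.
    """
    import mne

    path = Path(path)
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    labels = tuple(raw.ch_names)

    montage = Montage.from_tsv(montage_path) if montage_path else Montage.standard()
    unmapped = [ch for ch in labels if ch not in montage.labels]
    if unmapped:
        raise ValueError(f"channels not in montage: {unmapped}")
    order = [labels.index(ch) for ch in montage.labels]
    data = data[order]

    events: list[tuple[int, str]] = []
    if events_path is not None:
        events, meta = read_events_tsv(events_path)
        n_true = int(meta.get("n_samples", data.shape[1]))
        if n_true > data.shape[1]:
            raise ValueError("event sidecar claims more samples than the EDF holds")
        data = data[:, :n_true]
        for sample, code in events:
            if not 0 <= sample < n_true:
                raise ValueError(f"event sample {sample} outside recording of {n_true}")
    return Recording(data=data, rate=float(raw.info["sfreq"]), montage=montage, events=events)


# --------------------------------------------------------------------------
# Epochs container (binary arrays + JSON metadata; runtime artefacts only)
# --------------------------------------------------------------------------


def save_epochs(epochs: Epochs, path) -> None:
    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        data=epochs.data,
        rejected=epochs.rejected,
        target=np.array([]) if epochs.target is None else epochs.target,
        correct=np.array([]) if epochs.correct is None else epochs.correct,
    )
    meta = {
        "rate": epochs.rate,
        "window_ms": list(epochs.window_ms),
        "conditions": list(epochs.conditions),
        "bad_channels": sorted(epochs.bad_channels),
        "montage_labels": list(epochs.montage.labels),
        "montage_positions": epochs.montage.positions.tolist(),
        "montage_is_scalp": epochs.montage.is_scalp.tolist(),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh)


def load_epochs(path) -> Epochs:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"), allow_pickle=False)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    montage = Montage(
        tuple(meta["montage_labels"]),
        np.array(meta["montage_positions"]),
        np.array(meta["montage_is_scalp"]),
    )
    target = arrays["target"] if arrays["target"].size else None
    correct = arrays["correct"] if arrays["correct"].size else None
    return Epochs(
        data=arrays["data"],
        rate=meta["rate"],
        window_ms=tuple(meta["window_ms"]),
        conditions=np.array(meta["conditions"], dtype=object),
        montage=montage,
        rejected=arrays["rejected"],
        bad_channels=frozenset(meta["bad_channels"]),
        target=target,
        correct=correct,
    )
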