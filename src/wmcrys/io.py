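"""Cohort container I/O, pipeline orchestration and summary reports.

Layout conventions: HDF5 for tensors (``/animal/<id>/day/<d>/...`` with the
per-day trial table serialized as CSV text inside the group), CSV for stage
tables, YAML for configuration snapshots, JSON for run manifests.  Units are
micrometres for space and seconds for time; day indices are 1-based.

All randomness flows from one master seed; deterministic stages produce
byte-identical CSV outputs across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _stdio
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import behaviour as behaviour_mod
from . import decoding as decoding_mod
from . import registration as registration_mod
from . import selectivity as selectivity_mod
from . import stability as stability_mod
from .synthetic import Cohort, GeneratorConfig, GroundTruth, generate_cohort
from .task_model import (Session, TaskConfig, Trial, bin_activity,
                         build_epoch_windows, labels_for)

logger = logging.getLogger("wmcrys.io")

STAGES = ("simulate", "behaviour", "selectivity", "registration", "decoding",
          "stability")


# ---------------------------------------------------------------------------
# trial table <-> CSV
# ---------------------------------------------------------------------------

def trials_to_csv(trials: Sequence[Trial]) -> str:
    rows = [{"trial_index": i, "trial_type": t.trial_type,
             "licked": int(t.licked), "outcome": t.outcome,
             "lick_times": ";".join(f"{x:g}" for x in t.lick_times)}
            for i, t in enumerate(trials)]
    buf = _stdio.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()


def trials_from_csv(text: str) -> list[Trial]:
    df = pd.read_csv(_stdio.StringIO(text),
                     dtype={"lick_times": str}, keep_default_na=False)
    for col in ("trial_index", "trial_type", "licked"):
        if col not in df.columns:
            raise ValueError(f"trial table missing column {col!r}")
    out = []
    for _, row in df.sort_values("trial_index").iterrows():
        lt = tuple(float(x) for x in str(row["lick_times"]).split(";") if x)
        out.append(Trial(trial_type=row["trial_type"],
                         licked=bool(int(row["licked"])), lick_times=lt))
    return out


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        f.attrs["task_config"] = json.dumps(dataclasses.asdict(cohort.task))
        root = f.create_group("animal")
        for s in cohort.sessions:
            g = root.require_group(s.animal_id).require_group("day") \
                    .create_group(str(s.day_index))
            g.create_dataset("activity", data=s.activity)
            g.create_dataset("centroids", data=s.centroids)
            g.create_dataset("neuron_ids",
                             data=np.asarray(s.neuron_ids, dtype=np.int64))
            if s.locomotion is not None:
                g.create_dataset("locomotion", data=s.locomotion)
            g.create_dataset("trials_csv", data=trials_to_csv(s.trials))
            g.attrs["day_index"] = s.day_index
            g.attrs["frame_rate"] = (s.frame_rate
                                     or cohort.task.frame_rate)


def read_cohort(path) -> Cohort:
    """Read a cohort back; round-trip identity with :func:`write_cohort`."""
    with h5py.File(path, "r") as f:
        if "task_config" not in f.attrs:
            raise ValueError("container missing attribute 'task_config'")
        task = TaskConfig(**json.loads(f.attrs["task_config"]))
        if "animal" not in f:
            raise ValueError("container missing group 'animal'")
        sessions = []
        for animal_id in sorted(f["animal"]):
            days_grp = f[f"animal/{animal_id}"]
            if "day" not in days_grp:
                raise ValueError(f"animal {animal_id!r} missing group 'day'")
            for d in sorted(days_grp["day"], key=int):
                g = days_grp[f"day/{d}"]
                for name in ("activity", "centroids", "neuron_ids",
                             "trials_csv"):
                    if name not in g:
                        raise ValueError(
                            f"animal {animal_id!r} day {d} missing "
                            f"dataset {name!r}")
                loco = g["locomotion"][()] if "locomotion" in g else None
                sessions.append(Session(
                    animal_id=animal_id, day_index=int(d),
                    trials=trials_from_csv(
                        g["trials_csv"][()].decode()
                        if isinstance(g["trials_csv"][()], bytes)
                        else str(g["trials_csv"][()])),
                    activity=g["activity"][()],
                    centroids=g["centroids"][()],
                    neuron_ids=g["neuron_ids"][()],
                    locomotion=loco,
                    frame_rate=float(g.attrs["frame_rate"])))
    return Cohort(sessions=sessions, task=task)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_config_yaml(config, path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def read_generator_config(path) -> GeneratorConfig:
    raw = yaml.safe_load(Path(path).read_text())
    task = TaskConfig(**raw.pop("task")) if "task" in raw else TaskConfig()
    if "frac_selective" in raw:
        raw["frac_selective"] = dict(raw["frac_selective"])
    if "depth_range" in raw:
        raw["depth_range"] = tuple(raw["depth_range"])
    return GeneratorConfig(task=task, **raw)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PipelineOptions:
    """Pipeline-stage knobs (analysis choices, not generator conditions)."""

    decode_epochs: tuple[str, ...] = ("first_odour", "late_delay", "choice")
    crossday_epoch: str = "late_delay"
    field_epochs: tuple[str, ...] = ("first_odour", "early_delay",
                                     "late_delay", "choice")
    field_shuffles: int = 1000
    chance_shuffles: int = 5
    n_repeats: int = 32
    day_shuffle_perms: int = 1000
    max_dist_um: float = registration_mod.DEFAULT_MAX_DIST_UM


def default_blocks(days: Sequence[int]) -> tuple[tuple, tuple]:
    """Early/late day blocks: first and last halves (1-3 vs 5-7 for 7 days,
    1-5 vs 6-10 for 10 days)."""
    days = sorted(days)
    k = len(days) // 2
    return tuple(days[:k]), tuple(days[-k:])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: GeneratorConfig, out_dir,
                 seed: Optional[int] = None,
                 stages: Optional[Sequence[str]] = None,
                 options: PipelineOptions = PipelineOptions()) -> dict:
    """Run the analysis pipeline end to end and write stage outputs.

    ``stages`` selects a subset of :data:`STAGES`; later stages read earlier
    stages' outputs from ``out_dir`` (so a previous run can be resumed).
    Returns the run manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    master = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(np.random.default_rng(child).integers(2 ** 31))
                   for name, child in zip(STAGES, master.spawn(len(STAGES)))}
    windows = build_epoch_windows(config.task)
    manifest: dict = {"config": _to_plain(config), "seed": config.seed,
                      "stages": stages, "stage_seeds": stage_seeds,
                      "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
                      "outputs": {}}

    def _done(name: str, *paths: Path) -> None:
        manifest["outputs"][name] = {p.name: _sha256(p) for p in paths}
        logger.info("[%s] wrote %s", name, ", ".join(p.name for p in paths))

    cohort: Optional[Cohort] = None

    def _cohort() -> Cohort:
        nonlocal cohort
        if cohort is None:
            h5 = out / "cohort.h5"
            if not h5.exists():
                raise FileNotFoundError(
                    "cohort.h5 not found; run the 'simulate' stage first or "
                    "place a cohort container in the output directory")
            cohort = read_cohort(h5)
        return cohort

    if "simulate" in stages:
        logger.info("[simulate] generating cohort (seed=%d)", config.seed)
        cohort, gt = generate_cohort(config)
        write_cohort(cohort, out / "cohort.h5")
        gt.tuning.to_csv(out / "ground_truth.csv", index=False)
        write_config_yaml(config, out / "config.yaml")
        _done("simulate", out / "ground_truth.csv", out / "config.yaml")

    if "behaviour" in stages:
        rows = []
        for s in _cohort().sessions:
            b = behaviour_mod.performance(s.trials, day_index=s.day_index)
            rows.append({"animal_id": s.animal_id, "day": s.day_index,
                         **dataclasses.asdict(b)})
        pd.DataFrame(rows).to_csv(out / "behaviour.csv", index=False)
        _done("behaviour", out / "behaviour.csv")

    if "selectivity" in stages:
        sel_rows, prof_rows, field_rows = [], [], []
        ss = np.random.SeedSequence(stage_seeds["selectivity"])
        children = iter(ss.spawn(len(_cohort().sessions)))
        for s in _cohort().sessions:
            child = np.random.default_rng(next(children))
            tensor = bin_activity(s, _cohort().task)
            grid = selectivity_mod.selectivity_grid(tensor, windows, s.trials)
            grid.insert(0, "animal_id", s.animal_id)
            grid.insert(1, "day", s.day_index)
            grid["neuron_id"] = np.asarray(s.neuron_ids)[grid["neuron_index"]]
            sel_rows.append(grid)
            prof = selectivity_mod.classify_profile(grid)
            prof.insert(0, "animal_id", s.animal_id)
            prof.insert(1, "day", s.day_index)
            prof["neuron_id"] = np.asarray(s.neuron_ids)[prof["neuron_index"]]
            prof_rows.append(prof)
            for ep in options.field_epochs:
                af = selectivity_mod.activity_field_test(
                    s, _cohort().task, windows, ep,
                    n_shuffles=options.field_shuffles,
                    seed=int(child.integers(2 ** 31)))
                af.insert(0, "animal_id", s.animal_id)
                af.insert(1, "day", s.day_index)
                field_rows.append(af)
        pd.concat(sel_rows).to_csv(out / "selectivity.csv", index=False)
        pd.concat(prof_rows).to_csv(out / "profiles.csv", index=False)
        pd.concat(field_rows).to_csv(out / "activity_fields.csv", index=False)
        _done("selectivity", out / "selectivity.csv", out / "profiles.csv",
              out / "activity_fields.csv")

    if "registration" in stages:
        rows = []
        co = _cohort()
        for animal in co.animals():
            days = co.days(animal)
            for di, dj in zip(days[:-1], days[1:]):
                t = registration_mod.match_sessions(
                    co.session(animal, di), co.session(animal, dj),
                    max_dist=options.max_dist_um)
                for _, r in t.pairs.iterrows():
                    rows.append({"animal_id": animal, "day_i": di,
                                 "day_j": dj, "id_i": int(r["id_i"]),
                                 "id_j": int(r["id_j"]),
                                 "distance": r["distance"]})
        pd.DataFrame(rows).to_csv(out / "matches.csv", index=False)
        _done("registration", out / "matches.csv")

    if "decoding" in stages:
        dcfg = decoding_mod.DecodingConfig(n_repeats=options.n_repeats)
        ss = np.random.SeedSequence(stage_seeds["decoding"])
        children = iter(ss.spawn(len(_cohort().sessions)))
        rows = []
        for s in _cohort().sessions:
            child = np.random.default_rng(next(children))
            tensor = bin_activity(s, _cohort().task)
            for kind in ("first_odour", "choice"):
                eps = [e for e in options.decode_epochs
                       if (e == "choice") == (kind == "choice")]
                if not eps:
                    continue
                labels = labels_for(s.trials, kind)
                res = decoding_mod.same_day_decoding(
                    tensor, labels, windows, dcfg,
                    seed=int(child.integers(2 ** 31)), epochs=eps)
                chance = decoding_mod.shuffle_chance(
                    tensor, labels, windows, dcfg,
                    n_shuffles=options.chance_shuffles,
                    seed=int(child.integers(2 ** 31)), epochs=eps)
                for ep in eps:
                    rows.append({"animal_id": s.animal_id, "day": s.day_index,
                                 "label_kind": kind, "epoch": ep,
                                 "accuracy": res.epoch_acc[ep],
                                 "sem": res.epoch_sem[ep],
                                 "chance_mean": chance[ep].mean,
                                 "chance_lo": chance[ep].lo,
                                 "chance_hi": chance[ep].hi,
                                 "n_neurons": res.n_neurons,
                                 "n_repeats": res.n_repeats})
        pd.DataFrame(rows).to_csv(out / "decoding_accuracy.csv", index=False)
        _done("decoding", out / "decoding_accuracy.csv")

    if "stability" in stages:
        co = _cohort()
        dcfg = decoding_mod.DecodingConfig(n_repeats=options.n_repeats)
        matrices = stability_mod.cohort_cross_day(
            co, windows, options.crossday_epoch, "first_odour", dcfg,
            seed=stage_seeds["stability"], max_dist=options.max_dist_um)
        rows = []
        for m in matrices:
            for i, di in enumerate(m.days):
                for j, dj in enumerate(m.days):
                    rows.append({"animal_id": m.animal_id, "epoch": m.epoch,
                                 "label_kind": m.label_kind,
                                 "train_day": int(di), "test_day": int(dj),
                                 "accuracy": m.acc[i, j],
                                 "n_matched": int(m.n_matched[i, j])})
        pd.DataFrame(rows).to_csv(out / "crossday_matrix.csv", index=False)
        days = list(matrices[0].days)
        early, late = default_blocks(days)
        result: dict = {"epoch": options.crossday_epoch,
                        "early_days": list(early), "late_days": list(late)}
        if len(early) >= 2 and len(late) >= 2:
            st = stability_mod.block_stability_stat(matrices, early, late)
            st.shuffle_p = stability_mod.day_shuffle_test(
                matrices, early, late, n_perm=options.day_shuffle_perms,
                seed=stage_seeds["stability"])
            result.update(difference=st.difference, t_stat=st.t_stat,
                          p_value=st.p_value, shuffle_p=st.shuffle_p,
                          early_means=list(st.early_means),
                          late_means=list(st.late_means))
        if len(days) >= 4:
            est = stability_mod.estimate_crystallization_day(
                stability_mod.mean_matrix(matrices),
                seed=stage_seeds["stability"])
            result["crystallization_day"] = est.day
            result["crystallization_band"] = (list(est.band)
                                              if est.band else None)
        (out / "stability_stats.json").write_text(
            json.dumps(_to_plain(result), indent=2, allow_nan=True))
        _done("stability", out / "crossday_matrix.csv",
              out / "stability_stats.json")

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(out_dir) -> str:
    """Markdown summary of the stage outputs present in ``out_dir``."""
    out = Path(out_dir)
    lines = ["# Pipeline summary", ""]

    beh = out / "behaviour.csv"
    if beh.exists():
        df = pd.read_csv(beh)
        lines += ["## Behaviour", "",
                  df.groupby("day")[["performance", "dprime"]].mean()
                    .round(3).to_markdown(), ""]
    else:
        lines += ["## Behaviour", "", "_missing (stage not run)_", ""]

    sel = out / "selectivity.csv"
    if sel.exists():
        df = pd.read_csv(sel)
        frac = (df.groupby(["epoch", "comparison"])["selective"].mean()
                  .rename("selective_fraction").round(3).reset_index())
        lines += ["## Selective fractions by epoch", "",
                  frac.to_markdown(index=False), ""]
    else:
        lines += ["## Selective fractions by epoch", "",
                  "_missing (stage not run)_", ""]

    dec = out / "decoding_accuracy.csv"
    if dec.exists():
        df = pd.read_csv(dec)
        agg = (df.groupby(["label_kind", "epoch"])
                 [["accuracy", "chance_mean"]].mean().round(3).reset_index())
        lines += ["## Decoding accuracy by epoch", "",
                  agg.to_markdown(index=False), ""]
    else:
        lines += ["## Decoding accuracy by epoch", "",
                  "_missing (stage not run)_", ""]

    stab = out / "stability_stats.json"
    if stab.exists():
        st = json.loads(stab.read_text())
        lines += ["## Cross-day stability", ""]
        for k in ("epoch", "early_days", "late_days", "difference",
                  "p_value", "shuffle_p", "crystallization_day"):
            if k in st:
                v = st[k]
                lines.append(f"- {k}: "
                             f"{round(v, 4) if isinstance(v, float) else v}")
        lines.append("")
    else:
        lines += ["## Cross-day stability", "", "_missing (stage not run)_",
                  ""]
    return "\n".join(lines)
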