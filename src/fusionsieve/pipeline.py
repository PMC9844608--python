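"""End-to-end orchestration: simulate/ingest -> consensus -> filter ->
annotate -> nominate -> stats -> quant/survival -> report.

A single structured config (YAML mapping or dict) drives the run; every
stage writes its table under the configured output directory and the run
manifest records per-stage row counts, the seed, and the stage order so a
rerun with the same config is byte-for-byte reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import __version__
from .chimera_annotation import (NominationConfig, NotExonicError, annotate_chimera,
                                 classify_type, nominate_driver, select_transcript)
from .cohort_filters import CascadeConfig, apply_cascade, classify_exclusivity
from .cohort_stats import AnnotatedEvent, percent, recurrence_table, tabulate
from .consensus import cross_validate, merge_events
from .formats_io import (read_caller_calls, read_domain_table, read_gtf,
                         read_sample_sheet, write_bedpe, write_canonical_calls)
from .fixtures import load_table1, load_table2_counts, table1_events
from .quant_survival import (CtRecord, SurvivalRecord, ddct, km_estimate,
                             logrank_test, rank_sum_test)
from .synthetic_cohort import SimulationConfig, simulate_bundle

__all__ = ["ConfigError", "RunManifest", "run_pipeline", "load_fixture",
           "fixture_nomination_report"]

STAGE_ORDER = ["simulate", "ingest", "consensus", "cascade", "annotate",
               "nominate", "stats", "quant", "survival", "report"]

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "simulate", "inputs", "consensus", "filters",
         "nominate", "quant"},
    "simulate": set(SimulationConfig.__dataclass_fields__) - {"catalog"},
    "inputs": {"calls_dir", "gtf", "domains", "sample_sheet", "ct_table",
               "survival_table"},
    "consensus": {"min_tools", "tol"},
    "filters": {"min_support", "target_class"},
    "nominate": {"score_threshold", "min_recurrence"},
    "quant": {"calibrator"},
}


class ConfigError(ValueError):
    """Config violates the documented schema."""


def _check_schema(cfg: dict) -> None:
    for section, allowed in _SCHEMA.items():
        sub = cfg if section == "" else cfg.get(section) or {}
        if not isinstance(sub, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key in sub:
            if key not in allowed:
                where = section or "top level"
                raise ConfigError(f"unknown config key {key!r} in {where}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either 'simulate' or 'inputs'")


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    seed: int
    version: str
    stage_order: list[str]
    config: dict
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: dict | str | Path, seed: Optional[int] = None) -> RunManifest:
    """Execute the full pipeline from a config dict or YAML path.

    ``seed`` overrides the config's seed.  Returns the manifest (also
    written to ``<outdir>/manifest.json``).
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    _check_schema(config)
    seed = int(seed if seed is not None else config.get("seed", 0))
    outdir = Path(config.get("outdir", "results/run"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, version=__version__,
                           stage_order=list(STAGE_ORDER), config=config)

    # -- simulate or locate inputs --------------------------------------
    if "simulate" in config:
        sim_cfg = SimulationConfig(**{**(config["simulate"] or {}), "seed": seed})
        sim_dir = outdir / "sim"
        ann, truths, sheet = simulate_bundle(sim_cfg, sim_dir)
        inputs = {
            "calls_dir": sim_dir / "calls", "gtf": sim_dir / "annotation.gtf",
            "domains": sim_dir / "domains.tsv",
            "sample_sheet": sim_dir / "sample_sheet.tsv",
            "ct_table": sim_dir / "ct_table.csv",
            "survival_table": sim_dir / "survival_table.csv",
        }
        manifest.counts["simulate_planted_fusions"] = len(truths)
    else:
        inputs = {k: Path(v) for k, v in config["inputs"].items()}
        for key in ("calls_dir", "gtf", "domains", "sample_sheet"):
            if key not in inputs:
                raise ConfigError(f"inputs.{key} is required")
            if not inputs[key].exists():
                raise ConfigError(f"input file missing: inputs.{key} = {inputs[key]}")

    models = read_gtf(inputs["gtf"])
    domains = read_domain_table(inputs["domains"])
    sheet = read_sample_sheet(inputs["sample_sheet"])

    # -- ingest ----------------------------------------------------------
    calls, skipped = [], 0
    for sample_dir in sorted(Path(inputs["calls_dir"]).iterdir()):
        if not sample_dir.is_dir():
            continue
        for f in sorted(sample_dir.glob("*.tsv")):
            got, skip = read_caller_calls(f, f.stem, sample_id=sample_dir.name)
            calls.extend(got)
            skipped += skip
    write_canonical_calls(calls, outdir / "canonical_calls.tsv")
    manifest.counts["ingest_calls"] = len(calls)
    manifest.counts["ingest_skipped_rows"] = skipped

    # -- consensus -------------------------------------------------------
    ccfg = config.get("consensus") or {}
    min_tools = int(ccfg.get("min_tools", 2))
    tol = int(ccfg.get("tol", 10))
    clusters = cross_validate(calls, min_tools=min_tools, tol=tol)
    events = merge_events(clusters, sheet, tol=tol)
    manifest.counts["consensus_clusters"] = len(clusters)
    manifest.counts["consensus_events"] = len(events)
    _write_events_tsv(events, outdir / "events.tsv")

    # -- cascade ---------------------------------------------------------
    fcfg = config.get("filters") or {}
    cascade_cfg = CascadeConfig(min_tools=min_tools,
                                min_support=int(fcfg.get("min_support", 5)),
                                breakpoint_tol=tol,
                                target_class=str(fcfg.get("target_class", "LM_unique")))
    passing, traces = apply_cascade(events, models, cascade_cfg)
    manifest.counts["cascade_passing"] = len(passing)
    with open(outdir / "filter_trace.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene5", "gene3", "exclusivity_class", "read_support",
                    "coding", "normal_exclusion", "exclusivity",
                    "failed_stage", "fail_reason"])
        for t in traces:
            w.writerow([t.gene5, t.gene3, t.exclusivity_class,
                        *(int(t.stage_pass[s]) for s in
                          ("read_support", "coding", "normal_exclusion", "exclusivity")),
                        t.failed_stage or "", t.fail_reason or ""])
    write_bedpe(passing, outdir / "passing_events.bedpe")

    # -- annotate (all non-normal events, for stats) ----------------------
    annotated: dict[tuple, tuple[AnnotatedEvent, Any]] = {}
    for ev in events:
        cls = classify_exclusivity(ev)
        if cls == "normal_present":
            continue
        chim = None
        tx5 = select_transcript(models, ev.gene5)
        tx3 = select_transcript(models, ev.gene3)
        coding = bool(tx5 and tx3 and tx5.is_coding and tx3.is_coding)
        in_frame = False
        if tx5 and tx3:
            try:
                chim = annotate_chimera(ev.bp5, ev.bp3, tx5, tx3)
                coding = chim.frame_status != "noncoding" and coding
                in_frame = (chim.frame_status == "in_frame"
                            or (chim.frame_status == "five_prime_utr_fusion"
                                and bool(chim.intact_3p_orf)))
            except (NotExonicError, ValueError):
                coding = False
        annotated[ev.key] = (AnnotatedEvent(
            gene5=ev.gene5, gene3=ev.gene3, exclusivity_class=cls,
            fusion_type=classify_type(ev.bp5, ev.bp3),
            coding=coding, in_frame=in_frame), chim)
    manifest.counts["annotated_events"] = len(annotated)

    # -- nominate (cascade-passing events only) ---------------------------
    ncfg = config.get("nominate") or {}
    nom_cfg = NominationConfig(score_threshold=float(ncfg.get("score_threshold", 0.8)),
                               min_recurrence=int(ncfg.get("min_recurrence", 2)))
    nominations = []
    for ev in passing:
        entry = annotated.get(ev.key)
        if entry is None or entry[1] is None:
            continue
        ann_ev, chim = entry
        nom = nominate_driver(ev, chim, domains, driver_score=None,
                              recurrence_mCRC=ev.n_samples("LM"), config=nom_cfg)
        nominations.append((ev, chim, nom))
    n_nom = sum(1 for _, _, n in nominations if n.nominated)
    manifest.counts["nominated_drivers"] = n_nom
    with open(outdir / "annotation_report.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene5", "gene3", "tx5", "tx3", "exon5", "exon3", "phase5",
                    "phase3", "frame_status", "preserved_domains", "driver_score",
                    "recurrence", "nominated", "reasons"])
        for ev, chim, nom in nominations:
            w.writerow([ev.gene5, ev.gene3, chim.tx5, chim.tx3,
                        chim.junction_exon5, chim.junction_exon3,
                        chim.phase5, chim.phase3, chim.frame_status,
                        ";".join(f"{p}:{d.name}" for p, d in nom.preserved),
                        "" if nom.driver_score is None else nom.driver_score,
                        nom.recurrence_mCRC, int(nom.nominated),
                        "; ".join(nom.reasons)])

    # -- stats -----------------------------------------------------------
    counts = tabulate(a for a, _ in annotated.values())
    _write_counts_tsv(counts, outdir / "counts.tsv")
    rec = recurrence_table(events, sheet)
    with open(outdir / "recurrence.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene5", "gene3", "n_LM_samples"])
        w.writerows(rec)

    # -- quant -----------------------------------------------------------
    if inputs.get("ct_table") and Path(inputs["ct_table"]).exists():
        qcfg = config.get("quant") or {}
        records = _read_ct(inputs["ct_table"])
        rel = ddct(records, calibrator=str(qcfg.get("calibrator", "pCRC")))
        with open(outdir / "rq_table.tsv", "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["sample_id", "group", "delta_ct", "ddct", "rq"])
            for r in rel:
                w.writerow([r.sample_id, r.group, f"{r.delta_ct:.4f}",
                            f"{r.ddct:.4f}", f"{r.rq:.4f}"])
        x = [r.rq for r in rel if r.group == "mCRC"]
        y = [r.rq for r in rel if r.group == "pCRC"]
        u, p = rank_sum_test(x, y)
        manifest.counts["quant_samples"] = len(rel)
        _write_json(outdir / "expression_test.json",
                    {"U": u, "p_value": p, "n_mCRC": len(x), "n_pCRC": len(y)})

    # -- survival ---------------------------------------------------------
    if inputs.get("survival_table") and Path(inputs["survival_table"]).exists():
        surv = _read_survival(inputs["survival_table"])
        res = logrank_test(surv)
        for label, grp in (("positive", True), ("negative", False)):
            km = km_estimate(surv, group=grp)
            with open(outdir / f"km_{label}.tsv", "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(["time", "survival", "n_at_risk", "n_events"])
                for t, s, n, d in zip(km.times, km.survival, km.n_at_risk, km.n_events):
                    w.writerow([f"{t:.4f}", f"{s:.6f}", n, d])
        manifest.counts["survival_records"] = len(surv)
        _write_json(outdir / "survival_test.json",
                    {"chi_square": res.chi_square, "p_value": res.p_value,
                     "observed": list(res.observed), "expected": list(res.expected)})

    manifest.write(outdir / "manifest.json")
    return manifest


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_events_tsv(events, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene5", "gene3", "chrom5", "pos5", "strand5", "chrom3",
                    "pos3", "strand3", "n_callers_max", "n_samples_LM",
                    "n_samples_pCRC", "n_samples_N", "max_support"])
        for ev in events:
            w.writerow([ev.gene5, ev.gene3, ev.bp5.chrom, ev.bp5.pos, ev.bp5.strand,
                        ev.bp3.chrom, ev.bp3.pos, ev.bp3.strand, ev.max_callers,
                        ev.n_samples("LM"), ev.n_samples("pCRC"), ev.n_samples("N"),
                        ev.max_support])


def _write_counts_tsv(counts, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["exclusivity_class", "category", "count", "pct"])
        for cls, c in counts.counts.items():
            total = counts.total(cls)
            for cat, n in c.items():
                pct = percent(n, total, 1) if total else 0.0
                w.writerow([cls, cat, n, pct])


def _read_ct(path) -> list[CtRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    return [CtRecord(sample_id=str(r["sample_id"]), group=str(r["group"]),
                     target_ct=float(r["target_ct"]),
                     reference_ct=float(r["reference_ct"]))
            for _, r in df.iterrows()]


def _read_survival(path) -> list[SurvivalRecord]:
    import pandas as pd

    df = pd.read_csv(path)
    return [SurvivalRecord(sample_id=str(r["sample_id"]),
                           time=float(r["time_months"]), event=int(r["event"]),
                           fusion_positive=bool(int(r["fusion_positive"])))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

FIXTURES = ("table1", "table2_counts")


def load_fixture(name: str):
    """Load a packaged worked-example fixture by name."""
    if name == "table1":
        return load_table1()
    if name == "table2_counts":
        return load_table2_counts()
    raise KeyError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")


def fixture_nomination_report() -> list[dict]:
    """Driver nomination over the packaged fourteen-fusion fixture.

    All fixture rows carry a functional domain and recur in >= 2
    metastatic samples, so all fourteen are nominated; recurrence is
    recomputed from the carrier sample lists.
    """
    rows = load_table1()
    events = table1_events()
    report = []
    for row, ev in zip(rows, events):
        rec = ev.n_samples("LM")
        report.append({
            "gene5": row.gene5, "gene3": row.gene3,
            "fusion_type": row.fusion_type,
            "functional_domain": row.functional_domain,
            "recurrence_mCRC": rec,
            "max_support": ev.max_support,
            "nominated": bool(row.functional_domain) and rec >= 2,
        })
    return report
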