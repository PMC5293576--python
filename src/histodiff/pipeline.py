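"""Single-process pipeline orchestration with a deterministic manifest.

Stages run in dependency order (simulate -> pileup -> profiles ->
diff-peaks -> amplify -> report); each writes its artifacts and a manifest
entry recording parameters and SHA-256 hashes of inputs and outputs.  A
rerun with identical parameters and inputs skips a stage whose recorded
outputs are already present and unchanged ("cached").  Manifests contain
no timestamps, so identical runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import amplification as amp
from . import annotation, coverage, expression, peaks, profiles
from .simulate import SimulationConfig, simulate as _simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pileup", "profiles", "diff_peaks", "amplify", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "outdir" not in cfg:
        raise ValueError("pipeline config must set 'outdir'")
    return cfg


class _Manifest:
    """Stage records with outdir-relative paths and no timestamps, so two
    runs of the same configuration are byte-identical.  Run/cached statuses
    live outside the manifest file (they describe the run, not the result)."""

    def __init__(self, path: Path, outdir: Path):
        self.path = path
        self.outdir = outdir
        self.entries: dict[str, dict] = {}
        self.statuses: dict[str, str] = {}
        self.previous: dict[str, dict] = {}
        if path.exists():
            try:
                self.previous = {e["stage"]: e for e in json.loads(path.read_text())}
            except (json.JSONDecodeError, KeyError, TypeError):
                self.previous = {}

    def _rel(self, p) -> str:
        p = Path(p)
        try:
            return str(p.relative_to(self.outdir))
        except ValueError:
            return str(p)

    def _abs(self, name: str) -> Path:
        p = Path(name)
        return p if p.is_absolute() else self.outdir / p

    def is_cached(self, stage: str, params: dict, inputs: dict[str, str]) -> bool:
        prev = self.previous.get(stage)
        if prev is None or prev["params"] != params or prev["inputs"] != inputs:
            return False
        for name, digest in prev["outputs"].items():
            p = self._abs(name)
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def record(self, stage, params, inputs, outputs, status):
        self.entries[stage] = {
            "stage": stage,
            "params": params,
            "inputs": inputs,
            "outputs": outputs,
        }
        self.statuses[stage] = status

    def write(self):
        ordered = [self.entries[s] for s in STAGES if s in self.entries]
        self.path.write_text(json.dumps(ordered, indent=1, sort_keys=True) + "\n")


def _params(cfg: dict, section: str, defaults) -> dict:
    d = dataclasses.asdict(defaults) if dataclasses.is_dataclass(defaults) else dict(defaults)
    d.update(cfg.get(section) or {})
    return d


def run_pipeline(cfg: dict) -> tuple[Path, dict[str, str]]:
    """Run all stages; returns the manifest path and per-stage statuses
    ("run" or "cached").

    Raises ``PipelineError`` naming the failing stage on any error.
    """
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir / "manifest.json", outdir)
    state: dict = {}
    try:
        _stage_simulate(cfg, outdir, manifest, state)
        _stage_pileup(cfg, outdir, manifest, state)
        _stage_profiles(cfg, outdir, manifest, state)
        _stage_diff_peaks(cfg, outdir, manifest, state)
        _stage_amplify(cfg, outdir, manifest, state)
        _stage_report(cfg, outdir, manifest, state)
    except Exception as exc:
        raise PipelineError(f"stage {state.get('current', '?')} failed: {exc}") from exc
    manifest.write()
    for stage, status in manifest.statuses.items():
        logger.info("stage %s: %s", stage, status)
    return manifest.path, manifest.statuses


class PipelineError(RuntimeError):
    pass


def _finish(manifest, stage, params, inputs, out_paths, ran: bool):
    outputs = {manifest._rel(p): _sha256(Path(p)) for p in out_paths}
    inputs = {manifest._rel(k): v for k, v in inputs.items()}
    manifest.record(stage, params, inputs, outputs, "run" if ran else "cached")


def _input_paths(cfg: dict, outdir: Path) -> dict[str, Path]:
    if cfg.get("simulate", None) is not None or "inputs" not in cfg:
        fx = outdir / "fixture"
        return {
            "chrom_sizes": fx / "chrom.sizes",
            "genes": fx / "genes.bed12",
            "cpg": fx / "cpg.bed",
            "reads_control": fx / "reads_control.bed.gz",
            "reads_case": fx / "reads_case.bed.gz",
            "expression": fx / "expr.tsv",
        }
    return {k: Path(v) for k, v in cfg["inputs"].items()}


def _stage_simulate(cfg, outdir, manifest, state):
    state["current"] = "simulate"
    if cfg.get("simulate", None) is None and "inputs" in cfg:
        return  # external inputs supplied; nothing to simulate
    params = _params(cfg, "simulate", SimulationConfig())
    params["seed"] = int(cfg.get("seed", params.get("seed", 0)))
    sim_cfg = SimulationConfig(
        **{
            **params,
            "genome": tuple((c, int(l)) for c, l in params["genome"]),
            "amplified_region": (
                tuple(params["amplified_region"])
                if params["amplified_region"] is not None
                else None
            ),
        }
    )
    man_params = json.loads(json.dumps(params, default=list))
    if manifest.is_cached("simulate", man_params, {}):
        paths = _input_paths(cfg, outdir)
        out_paths = list(paths.values()) + [outdir / "fixture" / "truth.json"]
        _finish(manifest, "simulate", man_params, {}, out_paths, ran=False)
        return
    data = _simulate(sim_cfg)
    paths = data.write(outdir / "fixture")
    _finish(manifest, "simulate", man_params, {}, paths.values(), ran=True)


def _load_annotation(cfg, outdir, state):
    paths = _input_paths(cfg, outdir)
    sizes = annotation.read_chrom_sizes(paths["chrom_sizes"])
    state["sizes"] = sizes
    state["genes"] = annotation.read_gene_models(paths["genes"], sizes)
    state["cpg"] = annotation.read_cpg_islands(paths["cpg"], sizes)
    state["paths"] = paths
    return paths


def _stage_pileup(cfg, outdir, manifest, state):
    state["current"] = "pileup"
    paths = _load_annotation(cfg, outdir, state)
    params = _params(cfg, "shift", coverage.ShiftParams())
    params["dedup"] = bool(cfg.get("dedup", True))
    inputs = {
        manifest._rel(paths[k]): _sha256(paths[k])
        for k in ("chrom_sizes", "reads_control", "reads_case")
    }
    out_paths = {s: outdir / f"{s}.bedgraph" for s in ("control", "case")}
    state["track_paths"] = out_paths
    if manifest.is_cached("pileup", params, inputs):
        state["tracks"] = {
            s: coverage.read_bedgraph(p, state["sizes"]) for s, p in out_paths.items()
        }
        _finish(manifest, "pileup", params, inputs, out_paths.values(), ran=False)
        return
    shift = coverage.ShiftParams(
        shift_bp=int(params["shift_bp"]),
        extend_to=params["extend_to"],
        literal_5prime=bool(params["literal_5prime"]),
    )
    tracks = {}
    for s in ("control", "case"):
        readset = annotation.read_reads_bed(paths[f"reads_{s}"], state["sizes"])
        reads = readset.reads
        if params["dedup"]:
            reads, _ = amp.dedup_reads(reads)
        raw = coverage.pileup(reads, shift, state["sizes"])
        tracks[s] = coverage.normalize(raw)
        coverage.write_bedgraph(tracks[s], out_paths[s])
    state["tracks"] = tracks
    _finish(manifest, "pileup", params, inputs, out_paths.values(), ran=True)


def _stage_profiles(cfg, outdir, manifest, state):
    state["current"] = "profiles"
    params = _params(cfg, "profiles", {"half_window": 3000, "cpg_window": 500})
    inputs = {manifest._rel(p): _sha256(p) for p in state["track_paths"].values()}
    inputs[manifest._rel(state["paths"]["genes"])] = _sha256(state["paths"]["genes"])
    out_paths = [outdir / f"profile_{a}_{s}.tsv" for a in ("tss", "tts", "cpg") for s in ("control", "case")]
    stats_path = outdir / "profiles_stats.json"
    out_paths.append(stats_path)
    counts_paths = {s: outdir / f"tss_counts_{s}.tsv" for s in ("control", "case")}
    out_paths.extend(counts_paths.values())
    if manifest.is_cached("profiles", params, inputs):
        state["tss_counts"] = {
            s: _read_counts_tsv(p) for s, p in counts_paths.items()
        }
        state["cpg_ttest"] = _cpg_test_from_json(stats_path)
        _finish(manifest, "profiles", params, inputs, out_paths, ran=False)
        return
    genes, islands = state["genes"], state["cpg"]
    anchor_sets = {
        "tss": profiles.anchors_from_genes(genes, "tss"),
        "tts": profiles.anchors_from_genes(genes, "tts"),
        "cpg": profiles.anchors_from_cpg(islands),
    }
    for a, anchors in anchor_sets.items():
        for s, track in state["tracks"].items():
            mp = profiles.meta_profile(track, anchors, int(params["half_window"]))
            _write_profile_tsv(mp, outdir / f"profile_{a}_{s}.tsv")
    state["tss_counts"] = {}
    for s, track in state["tracks"].items():
        counts = profiles.tss_vicinity_counts(track, genes)
        state["tss_counts"][s] = counts
        _write_counts_tsv(counts, counts_paths[s])
    ttest = profiles.cpg_window_ttest(
        state["tracks"]["control"], state["tracks"]["case"], islands,
        window=int(params["cpg_window"]),
    )
    state["cpg_ttest"] = ttest
    stats_path.write_text(
        json.dumps(dataclasses.asdict(ttest), indent=1, sort_keys=True) + "\n"
    )
    _finish(manifest, "profiles", params, inputs, out_paths, ran=True)


def _stage_diff_peaks(cfg, outdir, manifest, state):
    state["current"] = "diff_peaks"
    params = _params(cfg, "caller", {"min_value": 4.0, "min_width": 200, "merge_gap": 50})
    params.update(_params(cfg, "scheme", peaks.RegionScheme()))
    params["promoter"] = cfg.get("promoter_window", "distal")
    inputs = {manifest._rel(p): _sha256(p) for p in state["track_paths"].values()}
    inputs[manifest._rel(state["paths"]["genes"])] = _sha256(state["paths"]["genes"])
    out = {
        "peaks_control": outdir / "peaks_control.bed",
        "peaks_case": outdir / "peaks_case.bed",
        "calls": outdir / "gain_loss.tsv",
        "overlap": outdir / "overlap_summary.json",
    }
    cached = manifest.is_cached("diff_peaks", params, inputs)
    scheme = peaks.RegionScheme(
        promoter_upstream=int(params["promoter_upstream"]),
        promoter_downstream=int(params["promoter_downstream"]),
        proximal_upstream=int(params["proximal_upstream"]),
        proximal_downstream=int(params["proximal_downstream"]),
    )
    peak_sets = {}
    if cfg.get("peak_files"):
        for s in ("control", "case"):
            peak_sets[s] = peaks.read_peaks(cfg["peak_files"][s], s, state["sizes"])
    else:
        for s in ("control", "case"):
            peak_sets[s] = peaks.standin_call_peaks(
                state["tracks"][s],
                sample_label=s,
                min_value=float(params["min_value"]),
                min_width=int(params["min_width"]),
                merge_gap=int(params["merge_gap"]),
            )
    counts = {
        s: peaks.assign_peaks(peak_sets[s], state["genes"], scheme, params["promoter"])
        for s in ("control", "case")
    }
    calls = peaks.classify_gain_loss(counts["control"], counts["case"])
    state["gain_loss"] = calls
    if cached:
        _finish(manifest, "diff_peaks", params, inputs, out.values(), ran=False)
        return
    for s in ("control", "case"):
        peaks.write_peaks_bed(peak_sets[s], out[f"peaks_{s}"])
    _write_calls_tsv(calls, out["calls"])
    summary = peaks.overlap_summary(peak_sets["control"], peak_sets["case"])
    out["overlap"].write_text(
        json.dumps(dataclasses.asdict(summary), indent=1, sort_keys=True, default=float)
        + "\n"
    )
    _finish(manifest, "diff_peaks", params, inputs, out.values(), ran=True)


def _stage_amplify(cfg, outdir, manifest, state):
    state["current"] = "amplify"
    params = _params(cfg, "amplification", amp.AmplificationParams())
    inputs = {manifest._rel(p): _sha256(p) for p in state["track_paths"].values()}
    out = {
        "regions": outdir / "amplified_regions.bed",
        "genes": outdir / "amplified_genes.tsv",
    }
    amp_params = amp.AmplificationParams(**{
        k: params[k]
        for k in (
            "min_width", "fold_over_case_mean", "fold_case_over_control",
            "fold_over_control_mean", "window", "step", "depth_scaling", "dedup",
        )
    })
    regions = amp.scan_amplified(
        state["tracks"]["case"], state["tracks"]["control"], amp_params,
        dedup_applied=bool(cfg.get("dedup", True)),
    )
    gene_table = amp.annotate_amplified(regions, state["genes"])
    state["amplified"] = (regions, gene_table)
    if manifest.is_cached("amplify", params, inputs):
        _finish(manifest, "amplify", params, inputs, out.values(), ran=False)
        return
    amp.write_amplified_bed(regions, out["regions"])
    with open(out["genes"], "w") as fh:
        fh.write("gene_id\tmin_p_value\n")
        for gid, p in sorted(gene_table.items()):
            fh.write(f"{gid}\t{p:.6e}\n")
    _finish(manifest, "amplify", params, inputs, out.values(), ran=True)


def _stage_report(cfg, outdir, manifest, state):
    state["current"] = "report"
    params = {"markers": list(cfg.get("markers", []))}
    expr_path = state["paths"]["expression"]
    inputs = {manifest._rel(expr_path): _sha256(expr_path)}
    inputs.update({manifest._rel(p): _sha256(p) for p in state["track_paths"].values()})
    out_path = outdir / "report.json"
    regions, gene_table = state["amplified"]
    expr = expression.read_expression_tsv(expr_path)
    corr = {}
    for s in ("control", "case"):
        try:
            res = expression.signal_expression_correlation(state["tss_counts"][s], expr)
            corr[s] = {"r": res.r, "n": res.n}
        except ValueError:
            corr[s] = {"r": None, "n": 0}
    evidence = amp.subgroup_evidence_report(
        state["tracks"]["case"],
        state["tracks"]["control"],
        state["genes"],
        params["markers"],
        gene_table,
        state["cpg_ttest"],
    )
    status_counts: dict[str, int] = {}
    for c in state["gain_loss"]:
        status_counts[c.status] = status_counts.get(c.status, 0) + 1
    report = {
        "signal_expression_correlation": corr,
        "gain_loss_status_counts": status_counts,
        "n_amplified_regions": len(regions),
        "evidence": evidence,
    }
    state["report"] = report
    if manifest.is_cached("report", params, inputs):
        _finish(manifest, "report", params, inputs, [out_path], ran=False)
        return
    out_path.write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    _finish(manifest, "report", params, inputs, [out_path], ran=True)


# ---------------------------------------------------------------------------
# small TSV helpers


def _write_profile_tsv(mp: profiles.MetaProfile, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tvalue\n")
        for o, v in zip(mp.offsets, mp.values):
            fh.write(f"{o}\t{v:.6f}\n")


def _write_counts_tsv(counts: dict[str, float], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\n")
        for gid in sorted(counts):
            fh.write(f"{gid}\t{counts[gid]:.6f}\n")


def _read_counts_tsv(path: Path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            gid, v = line.rstrip("\n").split("\t")
            out[gid] = float(v)
    return out


def _cpg_test_from_json(path: Path) -> profiles.WindowStatResult:
    d = json.loads(path.read_text())
    return profiles.WindowStatResult(**d)


def _write_calls_tsv(calls, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tstatus\tpromoter_control\texon_control\tgene_body_control\t"
            "promoter_case\texon_case\tgene_body_case\n"
        )
        for c in sorted(calls, key=lambda c: c.gene_id):
            ev = c.evidence
            fh.write(
                f"{c.gene_id}\t{c.status}\t"
                f"{ev['control']['promoter']}\t{ev['control']['exon']}\t{ev['control']['gene_body']}\t"
                f"{ev['case']['promoter']}\t{ev['case']['exon']}\t{ev['case']['gene_body']}\n"
            )
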