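"""End-to-end pipeline over synthetic or real inputs.

Stages run in a fixed order (synth, segment, decode, trace_stats,
compartments, architecture, simulate); each stage writes its artifacts plus
a manifest (inputs, seed, parameter hash) under the output directory, and a
machine-readable run summary ties the stages together. A stage failure
halts the pipeline with a stage-named error; artifacts of completed stages
are retained.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import tifffile

from . import architecture, decoding, imaging, io as nio, phantoms, simulator, tracing

logger = logging.getLogger("nucleotrace")

STAGES = ("synth", "segment", "decode", "trace_stats", "compartments", "architecture", "simulate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _manifest(outdir: Path, stage: str, cfg: dict, seed: int, t0: float, **extra) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "config_hash": nio.config_hash(cfg),
        "wall_s": round(time.time() - t0, 3),
        **extra,
    }
    (outdir / f"{stage}.manifest.json").write_text(json.dumps(payload, indent=2, default=str))
    logger.info("stage=%s seed=%d wall=%.2fs", stage, seed, payload["wall_s"])


def pipeline_run(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages on a synthetic scene; returns the summary.

    ``config`` keys: ``stages`` (subset of STAGES; default all), ``seed``,
    ``n_cells``, ``fov_shape``, ``thresholds`` (contact_nm, association_nm),
    ``simulate`` (preset, n_runs, n_accepted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    stages = cfg.get("stages", list(STAGES))
    seed = int(cfg.get("seed", 0))
    thresholds = cfg.get("thresholds", {})
    contact_nm = float(thresholds.get("contact_nm", tracing.CONTACT_THRESHOLD_NM))
    assoc_nm = float(thresholds.get("association_nm", architecture.ASSOCIATION_THRESHOLD_NM))
    summary: dict = {"config_hash": nio.config_hash(cfg), "seed": seed, "stages": {}}

    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        try:
            if stage == "synth":
                scores = phantoms.synthetic_compartment_scores()
                phantom, stacks = phantoms.gen_scene(
                    n_cells=int(cfg.get("n_cells", 9)),
                    fov_shape=tuple(cfg.get("fov_shape", (512, 512, 10))),
                    seed=seed,
                    scores=scores,
                )
                for name, stack in stacks.items():
                    tifffile.imwrite(outdir / f"{name}.tif", stack.voxels.astype(np.float32))
                nio.write_traces(phantom.true_traces, outdir / "true_traces.csv")
                state.update(phantom=phantom, stacks=stacks, scores=scores)
                _manifest(outdir, stage, cfg, seed, t0, n_cells=len(phantom.cell_centers))
            elif stage == "segment":
                labels = imaging.segment_cells(state["stacks"]["membrane"])
                tifffile.imwrite(outdir / "cell_labels.tif", labels.labels.astype(np.int32))
                state["labels"] = labels
                _manifest(
                    outdir, stage, cfg, seed, t0,
                    n_cells=int(len(labels.retained_labels)),
                    n_excluded=len(labels.excluded),
                )
            elif stage == "decode":
                cb_path = cfg.get("codebook")
                if cb_path is None:
                    raise ValueError("decode stage requires a 'codebook' path in the config")
                codebook = nio.read_codebook(cb_path)
                rna, beads, planted, drift = phantoms.gen_merfish_stacks(
                    codebook,
                    molecules_per_gene=int(cfg.get("molecules_per_gene", 30)),
                    seed=seed + 1,
                )
                bits = [decoding.binarize_round(s, cfg.get("rna_threshold", 60.0)) for s in rna]
                molecules = decoding.decode_pixels(bits, codebook)
                counts: dict[str, int] = {}
                for m in molecules:
                    counts[m.gene_id] = counts.get(m.gene_id, 0) + 1
                (outdir / "molecule_counts.json").write_text(json.dumps(counts, indent=2))
                state["molecules"] = molecules
                _manifest(outdir, stage, cfg, seed, t0, n_molecules=len(molecules))
            elif stage == "trace_stats":
                traces = state["phantom"].true_traces
                dm = tracing.mean_distance_matrix(traces, min_pairs=2)
                np.savetxt(outdir / "mean_distance_nm.csv", dm.mean_nm, delimiter=",")
                prob, _ = tracing.contact_probability_matrix(traces, contact_nm)
                np.savetxt(outdir / "contact_probability.csv", prob, delimiter=",")
                state["dm"] = dm
                _manifest(outdir, stage, cfg, seed, t0, n_traces=len(traces))
            elif stage == "compartments":
                regions = phantoms.gen_regions(state["scores"], seed=seed)
                result = tracing.compartment_scores(state["dm"], regions)
                np.savetxt(outdir / "compartment_scores.csv", result.scores, delimiter=",")
                state.update(regions=regions, comp=result)
                _manifest(
                    outdir, stage, cfg, seed, t0,
                    exponent=result.exponent, oriented=result.oriented,
                )
            elif stage == "architecture":
                traces = state["phantom"].true_traces
                scores = state["comp"].scores if "comp" in state else state["scores"]
                pis = []
                for t in traces:
                    pts = t.positions[t.present]
                    labels = scores[t.present] > 0
                    if labels.sum() < 4 or (~labels).sum() < 4:
                        continue
                    try:
                        pis.append(architecture.polarization_index(pts[labels], pts[~labels]).PI)
                    except architecture.DegenerateHullError:
                        continue
                surface, _ = architecture.chromosome_surface_ratio(traces)
                np.savetxt(outdir / "polarization_index.csv", np.asarray(pis), delimiter=",")
                np.savetxt(outdir / "surface_ratio.csv", surface, delimiter=",")
                _manifest(outdir, stage, cfg, seed, t0, n_chromosomes=len(pis))
            elif stage == "simulate":
                sim_cfg = cfg.get("simulate", {})
                res = simulator.simulate_ensemble(
                    state.get("scores", phantoms.synthetic_compartment_scores()),
                    sim_cfg.get("preset", "full"),
                    n_runs=int(sim_cfg.get("n_runs", 10)),
                    n_accepted=int(sim_cfg.get("n_accepted", 10000)),
                    base_seed=seed,
                )
                np.savetxt(outdir / "sim_pi.csv", res.pi_observed, delimiter=",")
                _manifest(
                    outdir, stage, cfg, seed, t0,
                    median_pi=float(np.nanmedian(res.pi_observed)),
                )
        except Exception as err:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, err) from err
        summary["stages"][stage] = json.loads((outdir / f"{stage}.manifest.json").read_text())

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
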