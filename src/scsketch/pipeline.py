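"""End-to-end orchestration: read -> preprocess -> embed -> cluster -> annotate."""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .annotation import (
    assign_cell_types,
    cluster_trajectory,
    rank_sum_markers,
    read_reference_markers,
)
from .embedding import EmbeddingConfig, embed, train_embedding
from .io import (
    ExpressionMatrix,
    filter_min_count,
    normalize_and_log,
    read_expression,
    write_results,
)
from .sketch import SketchConfig, build_skeleton, estimate_k_weighted_bic, sketch_kmeans

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    input_path: str | None = None
    input_format: str | None = None
    min_count: int = 1
    scale: float = 1e4
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    sketch: SketchConfig = field(default_factory=SketchConfig)
    k: int | None = None
    k_range: tuple[int, int] | None = None
    marker_p_max: float = 1e-6
    marker_fc_min: float = 1.5
    reference_markers_path: str | None = None
    outdir: str = "scsketch_run"
    seed: int = 0
    annotate: bool = True

    def __post_init__(self) -> None:
        if (self.k is None) == (self.k_range is None):
            raise ValueError("supply exactly one of k or k_range")


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest["timings"][name] = round(time.time() - self.t0, 3)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Timer()


def run_pipeline(
    cfg: RunConfig, matrix: ExpressionMatrix | None = None
) -> Path:
    """Run every stage and persist artifacts plus a manifest.

    A pre-loaded matrix may be passed directly in place of ``input_path``.
    Returns the run directory; artifacts from completed stages survive a
    later stage's failure.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "timings": {},
        "stages": [],
    }

    def checkpoint() -> None:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    try:
        with _stage(manifest, "read"):
            if matrix is None:
                if cfg.input_path is None:
                    raise ValueError("no input matrix or path given")
                matrix = read_expression(cfg.input_path, cfg.input_format)
            manifest["input_shape"] = list(matrix.values.shape)
        manifest["stages"].append("read")
        checkpoint()

        with _stage(manifest, "filter"):
            matrix = filter_min_count(matrix, cfg.min_count)
            manifest["filtered_shape"] = list(matrix.values.shape)
        manifest["stages"].append("filter")

        with _stage(manifest, "normalize"):
            lognorm = normalize_and_log(matrix, cfg.scale)
        manifest["stages"].append("normalize")
        checkpoint()

        with _stage(manifest, "embed"):
            emb_cfg = EmbeddingConfig(
                **{**asdict(cfg.embedding), "seed": cfg.seed}
            )
            model = train_embedding(lognorm, emb_cfg)
            embedding = embed(model, lognorm)
            manifest["embedding_dim"] = int(embedding.shape[1])
            manifest["final_joint_loss"] = (
                model.training_log["joint"][-1] if model.training_log["joint"] else None
            )
        manifest["stages"].append("embed")
        checkpoint()

        rng = np.random.default_rng(cfg.seed)
        k = cfg.k
        if cfg.k_range is not None:
            with _stage(manifest, "estimate_k"):
                lo, hi = cfg.k_range
                skel = build_skeleton(
                    embedding, cfg.sketch, rng,
                    target=cfg.sketch.skeleton_target or max(500, 20 * hi),
                )
                k, scores = estimate_k_weighted_bic(
                    skel, range(lo, hi + 1), rng, cfg.sketch
                )
                manifest["k_scores"] = {str(kk): v for kk, v in scores.items()}
            manifest["stages"].append("estimate_k")
        manifest["k"] = int(k)
        checkpoint()

        with _stage(manifest, "cluster"):
            result = sketch_kmeans(embedding, k, cfg.sketch, rng)
            manifest["inertia"] = result.inertia
            write_results(result.labels, embedding, outdir / "run",
                          cell_ids=lognorm.cell_ids)
        manifest["stages"].append("cluster")
        checkpoint()

        if cfg.annotate and len(np.unique(result.labels)) >= 2:
            with _stage(manifest, "markers"):
                markers = rank_sum_markers(
                    lognorm, result.labels, cfg.marker_p_max, cfg.marker_fc_min
                )
                markers.table.to_csv(outdir / "markers.tsv", sep="\t", index=False)
                manifest["n_marker_rows"] = int(len(markers.table))
            manifest["stages"].append("markers")

            if cfg.reference_markers_path:
                with _stage(manifest, "assign"):
                    reference = read_reference_markers(cfg.reference_markers_path)
                    assignments = assign_cell_types(
                        markers, reference, lognorm.n_genes
                    )
                    rows = [
                        {
                            "cluster": a.cluster, "cell_type": a.cell_type,
                            "overlap": a.overlap, "jaccard": a.jaccard,
                            "matching_rate": a.matching_rate, "pvalue": a.pvalue,
                        }
                        for a in assignments
                    ]
                    with open(outdir / "cell_types.tsv", "w") as fh:
                        fh.write("cluster\tcell_type\toverlap\tjaccard\t"
                                 "matching_rate\tpvalue\n")
                        for r in rows:
                            fh.write(
                                f"{r['cluster']}\t{r['cell_type']}\t{r['overlap']}\t"
                                f"{r['jaccard']:.6g}\t{r['matching_rate']:.6g}\t"
                                f"{r['pvalue']:.6g}\n"
                            )
                manifest["stages"].append("assign")

            with _stage(manifest, "trajectory"):
                traj = cluster_trajectory(embedding, result.labels)
                (outdir / "trajectory.nwk").write_text(traj.to_newick() + "\n")
            manifest["stages"].append("trajectory")
    finally:
        checkpoint()

    return outdir
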