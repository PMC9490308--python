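"""End-to-end pipeline: collapse -> barcode -> discriminate -> distances -> trees.

A :class:`RunConfig` fully determines a run; identical config + seed gives
byte-identical outputs.  Every artifact lands in ``out_dir`` together with a
``manifest.json`` recording inputs, seed, versions and the clamped-branch log,
so a run can be reconstructed from its output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping, Sequence

from . import barcoding, haplotyping, phylo, seq_io
from .distances import DistanceModel, blocks_from_panel, distance_matrix, write_long_format, write_phylip
from .errors import DataValidationError
from .seq_io import MarkerPanel

log = logging.getLogger("grassbarcode")

#: Marker subsets trees are built on for the canonical 4-marker panel:
#: nuclear ITS alone, the three plastid markers, and all four concatenated.
CANONICAL_DATASETS = {
    "ITS": ["ITS"],
    "3-cpDNA": ["matK", "rbcL", "trnL-F"],
    "4-DNA": ["ITS", "matK", "rbcL", "trnL-F"],
}


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on."""

    fasta_paths: Mapping[str, str]  # marker_id -> FASTA path, composite-code order
    taxonomy_path: str
    out_dir: str
    distance_model: DistanceModel | str = DistanceModel.K2P
    gamma_shape: float | None = None
    bootstrap_replicates: int = 1000
    seed: int = 0
    tree_datasets: Mapping[str, Sequence[str]] | None = None  # name -> marker ids

    def __post_init__(self) -> None:
        if self.bootstrap_replicates < 1:
            raise DataValidationError("bootstrap_replicates must be >= 1")


def _package_version() -> str:
    try:
        return version("grassbarcode")
    except PackageNotFoundError:
        return "unknown"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_datasets(
    config: RunConfig, marker_ids: Sequence[str]
) -> dict[str, list[str]]:
    if config.tree_datasets is not None:
        datasets = {k: list(v) for k, v in config.tree_datasets.items()}
    elif set(marker_ids) == set(CANONICAL_DATASETS["4-DNA"]):
        datasets = {k: list(v) for k, v in CANONICAL_DATASETS.items()}
    else:
        datasets = {"all": list(marker_ids)}
    for name, mids in datasets.items():
        unknown = set(mids) - set(marker_ids)
        if unknown:
            raise DataValidationError(
                f"tree dataset {name!r} references unknown marker(s): "
                f"{', '.join(sorted(unknown))}"
            )
    return datasets


def run_pipeline(config: RunConfig, panel: MarkerPanel | None = None) -> dict[str, Path]:
    """Execute the full analysis; returns the map of artifact names to paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log.info("stage seq_io: reading panel")
    if panel is None:
        panel = seq_io.read_panel(config.fasta_paths, config.taxonomy_path)

    log.info("stage haplotyping: collapsing %d markers", len(panel.markers))
    assignments = haplotyping.collapse_all(panel)
    artifacts["haplotypes"] = haplotyping.write_haplotype_table(
        assignments, out / "haplotypes.tsv"
    )

    log.info("stage barcoding: building composite codes")
    artifacts["barcodes"] = barcoding.write_barcode_table(
        panel, assignments, out / "barcodes.tsv"
    )
    report = barcoding.discrimination_report(panel, assignments)
    report_path = out / "discrimination.json"
    report_path.write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )
    artifacts["discrimination"] = report_path

    log.info("stage distances: %s model", DistanceModel(config.distance_model).value)
    blocks = blocks_from_panel(panel)
    for mid, block in blocks.items():
        matrix = distance_matrix(block, config.distance_model, config.gamma_shape)
        stem = seq_io._safe_filename(mid)
        artifacts[f"distances_{mid}"] = write_phylip(
            matrix, out / f"distances_{stem}.phylip"
        )
        artifacts[f"distances_long_{mid}"] = write_long_format(
            matrix, out / f"distances_{stem}.tsv"
        )

    datasets = _resolve_datasets(config, panel.marker_ids)
    clamp_log: dict[str, dict] = {}
    for name, mids in datasets.items():
        log.info(
            "stage phylo: NJ + %d bootstrap replicates on %s",
            config.bootstrap_replicates,
            name,
        )
        concat = phylo.concatenate({m: blocks[m] for m in mids}, mids)
        tree = phylo.bootstrap_support(
            concat,
            model=config.distance_model,
            replicates=config.bootstrap_replicates,
            seed=config.seed,
            gamma_shape=config.gamma_shape,
        )
        stem = seq_io._safe_filename(name)
        artifacts[f"tree_{name}"] = phylo.write_newick(tree, out / f"tree_{stem}.nwk")
        clamp_log[name] = {
            "n_clamped_branches": tree.n_clamped,
            "clamped_length_total": tree.clamped_total,
            "total_branch_length": tree.total_branch_length,
        }
        if tree.n_clamped:
            log.warning(
                "dataset %s: clamped %d negative branch estimate(s), total %.6g",
                name,
                tree.n_clamped,
                tree.clamped_total,
            )

    manifest = {
        "package_version": _package_version(),
        "python_version": platform.python_version(),
        "seed": config.seed,
        "bootstrap_replicates": config.bootstrap_replicates,
        "distance_model": DistanceModel(config.distance_model).value,
        "gamma_shape": config.gamma_shape,
        "inputs": {
            "taxonomy": {
                "path": str(config.taxonomy_path),
                "sha256": _sha256(Path(config.taxonomy_path))
                if Path(config.taxonomy_path).exists()
                else None,
            },
            "fasta": {
                mid: {
                    "path": str(p),
                    "sha256": _sha256(Path(p)) if Path(p).exists() else None,
                }
                for mid, p in config.fasta_paths.items()
            },
        },
        "tree_datasets": {k: list(v) for k, v in datasets.items()},
        "clamped_branches": clamp_log,
        "artifacts": {k: str(v) for k, v in sorted(artifacts.items())},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
        newline="\n",
    )
    artifacts["manifest"] = manifest_path
    return artifacts
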