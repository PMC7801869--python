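"""Stage orchestration shared by the CLI and programmatic callers.

Every stage writes plain TSV/JSON with a run-manifest hash in a ``#``
header so outputs are traceable and byte-reproducible for a fixed config
and inputs (the manifest JSON itself carries the only timestamp).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .consensus import (
    DiscrepancyReport,
    TopologyConstraints,
    TopologyModel,
    call_candidate_regions,
    cross_family_discrepancies,
    project_segments_to_columns,
    reconcile,
)
from .formats import (
    Alignment,
    Sequence,
    read_alignment,
    read_annotation_tsv,
    read_fasta,
    read_structure,
)
from .hydropathy import builtin_ensemble, import_predictions, write_predictions
from .motifs import column_conservation, motif_table, parse_pattern, scan_pattern
from .contacts import (
    ContactShellConfig,
    classify_shells,
    contacts_table,
    detect_coordination,
    detect_salt_bridges,
    min_distances,
    shell_report,
)

DEFAULTS = {
    "min_support": 0.5,
    "core_min_predictors": 3,
    "min_width": 8,
    "min_gap": 3,
    "max_gap_fraction": 0.5,
    "match_fraction": 0.8,
    "shell_radii": [5.0, 6.0, 7.0],
    "coordination_cutoff": 3.0,
    "salt_bridge_cutoff": 4.0,
    "n_term_side": "cytoplasmic",
    "c_term_side": "lumenal",
    "first_segment_signal_anchor": True,
    "predictors": "builtin",
    "seed": 0,
}

KNOWN_KEYS = set(DEFAULTS) | {
    "fasta", "alignment", "alignment_dialect", "structure", "masks",
    "motif_definitions", "ligand_name", "ion_name", "out_dir",
}


@dataclass
class PipelineConfig:
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update(self.values)
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(values=data)

    def canonical_json(self) -> str:
        return json.dumps(self.values, sort_keys=True, default=str)


@dataclass
class RunManifest:
    version: str
    config_hash: str
    input_checksums: dict[str, str]
    seed: int
    timestamp: str = ""

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"version": self.version, "config": self.config_hash,
             "inputs": self.input_checksums, "seed": self.seed},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"tool": "tmtopo", "version": self.version,
                 "config_hash": self.config_hash,
                 "input_checksums": self.input_checksums,
                 "seed": self.seed, "manifest_hash": self.hash,
                 "timestamp": self.timestamp},
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def build_manifest(config: PipelineConfig, input_paths: list) -> RunManifest:
    checksums = {}
    for p in input_paths:
        if p is None:
            continue
        p = Path(p)
        checksums[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return RunManifest(
        version=__version__,
        config_hash=hashlib.sha256(config.canonical_json().encode()).hexdigest()[:16],
        input_checksums=checksums,
        seed=int(config["seed"]),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )


def _header(manifest: RunManifest, params: dict) -> str:
    bits = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# tmtopo {__version__} manifest={manifest.hash} {bits}\n"


@dataclass
class FamilyResult:
    votes: object
    regions: list
    model: TopologyModel
    report: DiscrepancyReport


def predict_tm_stage(sequences: list[Sequence], config: PipelineConfig):
    if config["predictors"] == "builtin":
        return builtin_ensemble(sequences)
    mode = str(config["predictors"])
    if mode.startswith("import:"):
        path = mode.split(":", 1)[1]
        return [import_predictions(path, Path(path).stem, sequences)]
    raise ValueError(f"unknown predictors setting {config['predictors']!r}")


def consensus_stage(alignment: Alignment, outputs, config: PipelineConfig):
    votes = project_segments_to_columns(
        alignment, outputs, max_gap_fraction=float(config["max_gap_fraction"])
    )
    regions = call_candidate_regions(
        votes, alignment,
        min_support=float(config["min_support"]),
        core_min_predictors=int(config["core_min_predictors"]),
        min_width=int(config["min_width"]),
        min_gap=int(config["min_gap"]),
    )
    return votes, regions


def topology_stage(regions, alignment, config: PipelineConfig, masks=None):
    constraints = TopologyConstraints(
        n_term_side=str(config["n_term_side"]),
        c_term_side=str(config["c_term_side"]),
        masks=masks,
        first_segment_signal_anchor=bool(config["first_segment_signal_anchor"]),
    )
    return reconcile(regions, constraints, alignment)


def run_family_pipeline(
    sequences: list[Sequence],
    alignment: Alignment,
    config: PipelineConfig | None = None,
    masks=None,
) -> FamilyResult:
    """predict-tm -> consensus -> topology over one family alignment."""
    if config is None:
        config = PipelineConfig()
    outputs = predict_tm_stage(sequences, config)
    votes, regions = consensus_stage(alignment, outputs, config)
    model, report = topology_stage(regions, alignment, config, masks=masks)
    extra = cross_family_discrepancies(
        alignment, outputs, regions,
        support_threshold=float(config["min_support"]),
        first_segment_signal_anchor=False,
    )
    report.items.extend(extra.items)
    return FamilyResult(votes=votes, regions=regions, model=model, report=report)


# ---------------------------------------------------------------------------
# writers


def write_topology_tsv(model: TopologyModel, alignment: Alignment,
                       manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header(manifest, {"n_tm": model.n_tm,
                                    "n_term": model.n_term_side,
                                    "c_term": model.c_term_side}))
        fh.write("seq_id\ttm_index\tstart\tend\n")
        for idx, region in enumerate(model.tms, start=1):
            for sid in alignment.ids:
                if sid in region.span_by_seq:
                    s, e = region.span_by_seq[sid]
                    fh.write(f"{sid}\t{idx}\t{s}\t{e}\n")
        fh.write("# loops\n")
        for lp in model.loops:
            fh.write(f"# loop\tafter_tm={lp.after_tm}\tside={lp.side}\tname={lp.name}\n")


def write_topology_bed(model: TopologyModel, alignment: Alignment, path) -> None:
    """BED export: the one place 0-based half-open coordinates appear."""
    with open(path, "w") as fh:
        for idx, region in enumerate(model.tms, start=1):
            for sid in alignment.ids:
                if sid in region.span_by_seq:
                    s, e = region.span_by_seq[sid]
                    fh.write(f"{sid}\t{s - 1}\t{e}\tTM{idx}\n")


def contacts_stage(structure_path, config: PipelineConfig):
    structure = read_structure(structure_path)
    ligand_name = config.get("ligand_name", "DPM")
    ligand = structure.ligand_group(ligand_name)
    if not ligand:
        # fall back to the largest multi-atom hetero group
        multi = [r for r in structure.hetero_residues if len(r.atoms) > 1]
        if not multi:
            raise ValueError(f"no ligand group {ligand_name!r} in structure")
        ligand = [max(multi, key=lambda r: len(r.atoms))]
    radii = tuple(float(r) for r in config["shell_radii"])
    shell_config = ContactShellConfig(radii=radii,
                                      labels=tuple("ABCDEFG"[:len(radii)]))
    dists = min_distances(structure, ligand,
                          heavy_atoms_only=shell_config.heavy_atoms_only)
    contacts = classify_shells(dists, structure, shell_config)
    try:
        metal = detect_coordination(
            structure, cutoff=float(config["coordination_cutoff"])
        )
    except ValueError:
        metal = None
    bridges = detect_salt_bridges(
        structure, ligand, cutoff=float(config["salt_bridge_cutoff"])
    )
    return structure, contacts, metal, bridges


def motifs_stage(alignment: Alignment, model: TopologyModel,
                 definitions: list[tuple[str, str, str]],
                 config: PipelineConfig):
    conservation = column_conservation(
        alignment, max_gap_fraction=float(config["max_gap_fraction"])
    )
    hits = []
    for name, spec, region in definitions:
        pattern = parse_pattern(name, spec, region)
        hits.extend(scan_pattern(
            alignment, pattern, model,
            match_fraction=float(config["match_fraction"]),
            conservation=conservation,
        ))
    return conservation, hits, motif_table(hits, conservation)
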