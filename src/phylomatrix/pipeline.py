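"""End-to-end pipeline: simulate -> select -> tree-QC -> concatenate ->
occupancy filter -> recode -> saturation report.

Each stage reads the previous stage's files, so every stage is also runnable
standalone (see :mod:`phylomatrix.cli`).  A run writes every intermediate
under the output directory and finishes with ``run_manifest.json`` mapping
each produced file to its SHA-256 hash; identical config + seed reproduce
identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import simulate as sim
from .exceptions import ConfigurationError, PhylomatrixError
from .families import read_gene_fasta
from .homology import (SelectionConfig, read_blast_tabular,
                       select_candidates, resolve_orthologs, selection_report)
from .recoding import SCHEMES, recode
from .saturation import (p_distance_matrix, patristic_matrix, saturation_fit,
                         paired_distance_table)
from .supermatrix import (concatenate, completeness, occupancy_filter,
                          occupancy_report, write_fasta, write_phylip,
                          write_partitions)
from .treeqc import LongBranchPolicy, nj_gene_tree

logger = logging.getLogger("phylomatrix")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable configuration for a full pipeline run."""

    out_dir: str = "phylomatrix_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "select": True, "treeclean": True,
        "concat": True, "recode": True, "saturation": True,
    })
    simulation: dict = field(default_factory=dict)
    selection: dict = field(default_factory=dict)
    long_branch: dict = field(default_factory=dict)
    occupancy_threshold: float = 0.5
    recoding_scheme: str = "dayhoff6"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
        return path

    def sim_config(self) -> sim.SimulationConfig:
        kwargs = dict(self.simulation)
        for key in ("gene_length_range", "rate_classes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs.setdefault("seed", self.seed)
        return sim.SimulationConfig(**kwargs)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(**self.selection)

    def long_branch_policy(self) -> LongBranchPolicy:
        return LongBranchPolicy(**self.long_branch)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the path of the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    produced: list[Path] = []
    stage = "setup"
    try:
        scheme = SCHEMES.get(config.recoding_scheme)
        if config.stages.get("recode", True) and scheme is None:
            raise ConfigurationError(
                f"unknown recoding scheme {config.recoding_scheme!r}")

        dataset = None
        data_dir = out / "data"
        if config.stages.get("simulate", True):
            stage = "simulate"
            logger.info("simulating dataset")
            dataset = sim.simulate_dataset(config.sim_config())
            produced.append(sim.write_dataset(dataset, data_dir))
            produced.extend(sorted(data_dir.rglob("*.fasta")))
            produced.extend(sorted(data_dir.rglob("*.tsv")))
            produced.extend(sorted(data_dir.rglob("*.nwk")))

        families = {}
        hits = {}
        if any(config.stages.get(s, True)
               for s in ("select", "treeclean", "concat", "recode", "saturation")):
            stage = "load"
            for p in sorted((data_dir / "genes").glob("*.fasta")):
                fam = read_gene_fasta(p)
                families[fam.gene_id] = fam
            for p in sorted((data_dir / "hits").glob("*.hits.tsv")):
                gid = p.name.split(".")[0]
                hits[gid] = read_blast_tabular(p, gene_id=gid)
            if not families:
                raise PhylomatrixError(f"no gene FASTA files under {data_dir}")

        resolved_families = []
        if config.stages.get("select", True):
            stage = "select"
            logger.info("selecting orthologs for %d genes", len(families))
            sel_cfg = config.selection_config()
            policy = config.long_branch_policy()
            use_trees = config.stages.get("treeclean", True)
            reports = []
            for gid in sorted(families):
                fam = families[gid]
                cand = select_candidates(hits[gid], sel_cfg)
                trees = None
                if use_trees:
                    seqs = {}
                    for entries in fam.members.values():
                        for sid, seq in entries:
                            if any(sid in ids for ids in cand.values()):
                                seqs[sid] = seq
                    tree = nj_gene_tree(seqs)
                    trees = {gid: tree} if tree is not None else None
                resolved = resolve_orthologs(cand, trees, policy)
                reports.append(selection_report(cand, resolved, hits[gid]))
                sel = resolved.get(gid, {})
                if sel:
                    sub = fam.subset(sel)
                    # selected sequences keyed by taxon, one each
                    resolved_families.append(sub)
            import pandas as pd
            rep_path = out / "selection_report.tsv"
            reports = [r for r in reports if len(r)]
            pd.concat(reports, ignore_index=True).to_csv(
                rep_path, sep="\t", index=False)
            produced.append(rep_path)
        else:
            resolved_families = [families[g].single_copy()
                                 for g in sorted(families)]

        matrix = None
        if config.stages.get("concat", True):
            stage = "concat"
            universe = sorted(set().union(
                *(set(f.members) for f in resolved_families))) \
                if resolved_families else []
            kept = occupancy_filter(resolved_families,
                                    config.occupancy_threshold, universe)
            logger.info("occupancy filter kept %d/%d genes",
                        len(kept), len(resolved_families))
            matrix = concatenate(kept)
            produced.append(write_phylip(matrix, out / "supermatrix.phy"))
            produced.append(write_fasta(matrix, out / "supermatrix.fasta"))
            produced.append(write_partitions(matrix, out / "partitions.txt"))
            occ = occupancy_report(matrix)
            occ_path = out / "occupancy.json"
            with open(occ_path, "w") as fh:
                json.dump(occ, fh, indent=2, sort_keys=True)
                fh.write("\n")
            produced.append(occ_path)
            logger.info("supermatrix: %d taxa x %d columns, %.1f%% complete",
                        matrix.n_taxa, matrix.n_columns, completeness(matrix))

        if config.stages.get("recode", True) and matrix is not None:
            stage = "recode"
            recoded = recode(matrix, scheme)
            produced.append(write_phylip(recoded, out / "supermatrix.dayhoff6.phy"))

        if config.stages.get("saturation", True) and matrix is not None:
            stage = "saturation"
            tree_path = data_dir / "species_tree.nwk"
            if tree_path.exists():
                import dendropy
                tree = dendropy.Tree.get(path=str(tree_path), schema="newick")
                obs = p_distance_matrix(matrix)
                pat = patristic_matrix(tree)
                fit = saturation_fit(obs, pat)
                sat_path = out / "saturation.json"
                with open(sat_path, "w") as fh:
                    json.dump({"pairs_used": fit.pairs_used,
                               "slope": fit.slope,
                               "intercept": fit.intercept,
                               "r_squared": fit.r_squared}, fh, indent=2)
                    fh.write("\n")
                produced.append(sat_path)
                tbl_path = out / "saturation_pairs.tsv"
                paired_distance_table(obs, pat).to_csv(
                    tbl_path, sep="\t", index=False)
                produced.append(tbl_path)
                logger.info("saturation fit: R^2 = %.3f over %d pairs",
                            fit.r_squared, fit.pairs_used)
    except PhylomatrixError as exc:
        raise PhylomatrixError(f"stage {stage!r} failed: {exc}") from exc

    manifest_path = out / "run_manifest.json"
    uniq = sorted({p for p in produced if p.is_file()})
    manifest = {
        "seed": config.seed,
        "stages": {k: bool(v) for k, v in config.stages.items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in uniq},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest_path
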