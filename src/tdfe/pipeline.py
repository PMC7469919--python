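"""End-to-end pipeline: counts (files or synthetic) -> tensor -> HOSVD ->
treatment split -> per-context gene selection -> two-group validation ->
exports, with a reproducible run manifest.

The manifest (JSON) records the full configuration, package version, seed
and every decision parameter, so a run can be reproduced bit-for-bit on the
same inputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_counts import harmonize_genes, read_tissue_counts, write_tissue_counts
from .model import TensorFE
from .synthetic import SyntheticSpec, default_study_spec, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    input_dir: str | None = None          # directory of count files, or None
    synthetic: bool = False               # generate the default study dataset
    synthetic_spec: str | None = None     # YAML spec path (overrides default)
    seed: int = 0
    log_transform: bool = True
    pseudocount: float = 1.0
    contexts: list[int] | None = None     # l1 indices; None -> auto-scan
    max_auto_contexts: int = 6
    ell2_candidates: list[int] = field(default_factory=lambda: [2, 3])
    ell3: int = 1
    n_vectors: int = 1
    threshold: float = 0.01
    dominance: float = 0.5
    allow_singleton_contexts: bool = False
    signed_split: bool = True   # split sign-mixed tissue groups into signed contexts
    output_dir: str = "tdfe_output"

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if not 0 < self.dominance <= 1:
            raise ValueError("dominance must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _load_matrices(config: RunConfig, sample_map):
    input_dir = Path(config.input_dir)
    paths = sorted(input_dir.glob("*_count_*.txt")) + sorted(
        input_dir.glob("*_count_*.txt.gz")
    )
    if not paths:
        raise FileNotFoundError(f"no *_count_*.txt[.gz] files under {input_dir}")
    return [read_tissue_counts(p, sample_map) for p in paths]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; write artifacts + manifest to the output
    directory and return the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": asdict(config),
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    # -- input -----------------------------------------------------------
    truth = None
    if config.synthetic:
        stage("generate")
        if config.synthetic_spec:
            spec = SyntheticSpec.from_yaml(config.synthetic_spec)
            spec.seed = config.seed
        else:
            spec = default_study_spec(seed=config.seed)
        matrices, truth = generate_dataset(spec)
        sample_map = spec.sample_map()
        manifest["ground_truth"] = truth.groups and {
            label: {"n_genes": len(v["genes"]), "tissues": v["tissues"]}
            for label, v in truth.groups.items()
        }
    elif config.input_dir:
        stage("read")
        from .io_counts import SampleMap

        sm_path = Path(config.input_dir) / "sample_map.yaml"
        if sm_path.exists():
            with open(sm_path) as fh:
                d = yaml.safe_load(fh)
            sample_map = SampleMap(
                treatments=d["treatments"],
                controls=d.get("controls", []),
                n_replicates=d.get("n_replicates", 2),
            )
        else:
            spec = default_study_spec()
            sample_map = spec.sample_map()
        matrices = _load_matrices(config, sample_map)
    else:
        raise ValueError("config must set input_dir or synthetic=true")

    # -- tensor + decomposition ------------------------------------------
    stage("harmonize/assemble/standardize/hosvd")
    fe = TensorFE.from_count_matrices(
        matrices, sample_map,
        log_transform=config.log_transform, pseudocount=config.pseudocount,
    )
    results = fe.fit()
    (out / "summary.txt").write_text(results.summary() + "\n")
    ell1_report = [l1 for l1 in range(2, min(7, results.mode_ranks[0] + 1))]
    results.core_report(ell1_report, config.ell2_candidates,
                        config.ell3).to_csv(out / "core_table.tsv", sep="\t")

    # -- treatment axis ---------------------------------------------------
    stage("treatment-split")
    treat_split, treat_report = results.treatment_split()
    treat_report.to_csv(out / "treatment_plane.tsv", sep="\t", index=False)
    treat_split.to_frame().to_csv(out / "treatment_split.tsv", sep="\t", index=False)
    manifest["treatment_members"] = treat_split.members

    # -- contexts ----------------------------------------------------------
    stage("contexts")
    n_tissues = len(results.std_tensor.tissue_names)
    if config.contexts is None:
        candidates = range(2, min(config.max_auto_contexts,
                                  results.mode_ranks[0]) + 1)
    else:
        candidates = config.contexts
    contexts: dict[str, dict] = {}
    selections = []
    for ell1 in candidates:
        split = results.tissue_group(ell1, config.dominance)
        if len(split.members) == n_tissues:
            logger.info("l1=%d: no tissue contrast, skipped", ell1)
            continue
        if len(split.members) == 1 and not config.allow_singleton_contexts:
            logger.info("l1=%d: singleton group %s, flagged and skipped",
                        ell1, split.members)
            contexts[f"l1={ell1}"] = {"skipped": "singleton", "members": split.members}
            continue

        # a sign-mixed dominant group indicates a difference vector between
        # two equal-strength tissue groups; analyse each sign side separately
        loads = split.provenance["loadings"]
        member_signs = {np.sign(loads[t]) for t in split.members}
        sides = ["abs"]
        if config.signed_split and len(member_signs) > 1:
            sides = ["positive", "negative"]

        for side in sides:
            if side == "abs":
                side_split = split
            else:
                side_split = results.tissue_group(ell1, config.dominance, side=side)
                if not side_split.members:
                    continue
            sel = results.select_context(
                ell1, config.ell2_candidates, config.ell3,
                n_vectors=config.n_vectors, threshold=config.threshold,
                side=side, dominance=config.dominance,
            )
            label = sel.context_label
            selections.append(sel)
            safe = label.replace("+", "pos").replace("-", "neg")
            sel.export_table(out / f"genes_{safe}.tsv")
            sel.export_gene_list(out / f"genes_{safe}.txt")
            side_split.to_frame().to_csv(out / f"tissue_split_{safe}.tsv",
                                         sep="\t", index=False)

            ctx = {
                "ell1": ell1,
                "side": side,
                "tissue_members": side_split.members,
                "ell4_indices": sel.ell4_indices,
                "n_selected": sel.n_selected,
            }
            if sel.n_selected:
                tissue_test = results.two_group_test(sel, side_split)
                drug_test = results.two_group_test(sel, treat_split)
                ctx["tissue_t_p"] = tissue_test.t_p
                ctx["tissue_wilcoxon_p"] = tissue_test.wilcoxon_p
                ctx["treatment_t_p"] = drug_test.t_p
                ctx["treatment_wilcoxon_p"] = drug_test.wilcoxon_p
            if truth is not None:
                ctx["recovery"] = _score_recovery(sel, side_split, truth)
            contexts[label] = ctx
    manifest["contexts"] = contexts

    # per-context statistical-test table (tab-separated)
    rows = []
    for label, ctx in contexts.items():
        if "skipped" in ctx:
            continue
        rows.append({
            "context": label,
            "tissues": ";".join(ctx["tissue_members"]),
            "n_genes": ctx["n_selected"],
            "tissue_t_p": ctx.get("tissue_t_p"),
            "tissue_wilcoxon_p": ctx.get("tissue_wilcoxon_p"),
            "treatment_t_p": ctx.get("treatment_t_p"),
            "treatment_wilcoxon_p": ctx.get("treatment_wilcoxon_p"),
        })
    if rows:
        pd.DataFrame(rows).to_csv(out / "group_tests.tsv", sep="\t",
                                  index=False)

    # -- overlaps ----------------------------------------------------------
    if len(selections) >= 2:
        stage("overlap")
        regions, jaccard = results.overlap_table(selections)
        regions.to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        jaccard.to_csv(out / "jaccard.tsv", sep="\t")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _score_recovery(sel, split, truth) -> dict:
    """Match a selection to the planted group (or union of groups) sharing
    its tissue set, then score precision/recall of the selected genes
    against the matched planted gene set.

    Unions of planted groups are considered because equal-strength group
    pairs legitimately surface as one joint context (a sum vector over the
    union of their tissues).
    """
    from itertools import combinations

    candidates: dict[str, tuple[set, set]] = {
        label: (truth.tissues_of(label), truth.genes_of(label))
        for label in truth.groups
    }
    for a, b in combinations(sorted(truth.groups), 2):
        candidates[f"{a}+{b}"] = (
            truth.tissues_of(a) | truth.tissues_of(b),
            truth.genes_of(a) | truth.genes_of(b),
        )
    best_label, best_overlap = None, -1.0
    for label, (tissues, _) in candidates.items():
        inter = len(tissues & set(split.members))
        union = len(tissues | set(split.members))
        score = inter / union if union else 0.0
        if score > best_overlap:
            best_label, best_overlap = label, score
    planted = candidates[best_label][1]
    selected = sel.selected
    tp = len(planted & selected)
    precision = tp / len(selected) if selected else 0.0
    recall = tp / len(planted) if planted else 0.0
    return {
        "matched_group": best_label,
        "tissue_jaccard": best_overlap,
        "precision": precision,
        "recall": recall,
    }


def generate_to_dir(spec: SyntheticSpec, out_dir: str | Path,
                    gzip_files: bool = False) -> Path:
    """Write one count file per tissue plus a ground-truth sidecar table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrices, truth = generate_dataset(spec)
    suffix = ".txt.gz" if gzip_files else ".txt"
    for m in matrices:
        write_tissue_counts(m, out / f"synthetic_count_{m.tissue_name}{suffix}")
    rows = ["group\tgene\ttissues"]
    for label, v in truth.groups.items():
        tset = ";".join(v["tissues"])
        rows += [f"{label}\t{g}\t{tset}" for g in v["genes"]]
    (out / "ground_truth.tsv").write_text("\n".join(rows) + "\n")
    with open(out / "sample_map.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "treatments": spec.treatment_names,
                "controls": spec.control_treatments,
                "n_replicates": spec.n_replicates,
            },
            fh, sort_keys=False,
        )
    return out
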