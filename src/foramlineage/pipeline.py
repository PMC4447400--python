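"""Orchestration of the two analysis arms.

The morphometric arm maps raw aperture geometry into (PADR, SI)
morphospace, fits the two-group linear discriminant on the labelled
training zone, and classifies specimens from every zone.  The molecular
arm infers a GTR+I+G maximum-likelihood tree with bootstrap supports
for each configured outgroup scheme, roots it on the outgroup, extracts
the focal-clade supports and reports whether the ingroup topology is
identical across schemes.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import discriminant as lda
from .io_formats import (
    Alignment,
    MeasurementTable,
    read_fasta,
    read_measurement_table,
    serialize_newick,
)
from .morphometrics import build_morphospace, morphospace_frame
from .phylo_inference import (
    BootstrapSummary,
    OutgroupScheme,
    bootstrap_support,
    clade_support,
    estimate_model_params,
    nj_tree,
    pairwise_distances,
    root_with_outgroup,
)
from .phylo_model import GTRIGParams
from .synthetic_data import RUBER_CLADE_TAXA, TRILOBUS_CLADE_TAXA
from .tree import PhyloTree


@dataclass
class RunConfig:
    """Settings shared by the two arms; all randomness flows from seed."""

    measurement_paths: list = field(default_factory=list)
    alignment_path: Optional[str] = None
    training_zone: str = "M3"
    scheme_names: list = field(default_factory=list)
    n_bootstrap: int = 100
    seed: int = 0
    n_categories: int = 4
    branch_tol: float = 1e-6
    model_tol: float = 1e-5
    out_dir: Optional[str] = None


# ---------------------------------------------------------------------------
# Morphometric arm
# ---------------------------------------------------------------------------

@dataclass
class MorphReport:
    model: lda.DiscriminantModel
    boundary: lda.BoundaryLine
    classification: lda.ClassificationResult
    training_zone: str

    def summary_dict(self) -> dict:
        return {
            "training_zone": self.training_zone,
            "group_labels": list(self.model.group_labels),
            "weights_padr_si": [float(w) for w in self.model.weights],
            "intercept": float(self.model.intercept),
            "boundary_A_B_C": [float(c) for c in self.boundary.coefficients],
            "n_per_group": list(self.model.n_per_group),
        }


def run_morphometric_arm(
    tables: Union[Sequence[MeasurementTable], Sequence[str], Sequence[Path]],
    training_zone: str = "M3",
    out_dir: Optional[Union[str, Path]] = None,
) -> MorphReport:
    """Morphospace -> LDA on the training zone -> classify every zone."""
    loaded: list[MeasurementTable] = []
    for t in tables:
        loaded.append(t if isinstance(t, MeasurementTable) else read_measurement_table(t))
    if not loaded:
        raise ValueError("no measurement tables provided")
    merged = MeasurementTable(
        pd.concat([t.data for t in loaded], ignore_index=True),
        pd.concat([t.rejected for t in loaded], ignore_index=True),
    )
    points = build_morphospace(merged)

    training = [
        p for p in points if p.zone == training_zone and p.lineage is not None
    ]
    labels = sorted({p.lineage for p in training})
    if len(labels) < 2:
        raise ValueError(
            f"training zone {training_zone!r} needs two lineage-labelled "
            f"groups; found labels {labels}"
        )
    if len(labels) > 2:
        raise ValueError(f"more than two lineage labels in training zone: {labels}")
    g1 = [p for p in training if p.lineage == labels[0]]
    g2 = [p for p in training if p.lineage == labels[1]]
    model = lda.fit_lda(g1, g2, labels=(labels[0], labels[1]))
    boundary = lda.boundary_line(model)
    classification = lda.apply_to_zones(model, points)
    report = MorphReport(model, boundary, classification, training_zone)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        morphospace_frame(points).to_csv(out / "morphospace.csv", index=False)
        classification.per_specimen.to_csv(
            out / "classification_per_specimen.csv", index=False
        )
        classification.per_zone.to_csv(
            out / "classification_per_zone.csv", index=False
        )
        with open(out / "discriminant_model.json", "w") as fh:
            json.dump(report.summary_dict(), fh, indent=2)
    return report


def plot_morphospace(report: MorphReport, path: Union[str, Path]) -> None:
    """Optional scatter of the morphospace with the z = 0 boundary."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = report.classification.per_specimen
    fig, ax = plt.subplots(figsize=(6, 5))
    for label, color in zip(report.model.group_labels, ("tab:red", "tab:blue")):
        sub = df[df["assigned"] == label]
        ax.scatter(sub["padr"], sub["si"], s=12, alpha=0.6, label=label, c=color)
    a, b, c = report.boundary.coefficients
    xs = df["padr"]
    x0, x1 = float(xs.min()), float(xs.max())
    if abs(b) > 1e-12:
        ax.plot([x0, x1], [-(a * x0 + c) / b, -(a * x1 + c) / b], "k--", lw=1)
    else:
        ax.axvline(-c / a, color="k", ls="--", lw=1)
    ax.set_xlabel("PADR (aperture width / height)")
    ax.set_ylabel("SI (larger / smaller flanking angle)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Molecular arm
# ---------------------------------------------------------------------------

DEFAULT_FOCAL_CLADES = {
    "ruber_group_plus_rubescens": list(RUBER_CLADE_TAXA),
    "sacculifer_orbulina_sphaeroidinella": list(TRILOBUS_CLADE_TAXA),
}


@dataclass
class SchemeResult:
    scheme: OutgroupScheme
    params: GTRIGParams
    summary: BootstrapSummary
    rooted_tree: PhyloTree
    newick: str
    focal_supports: dict
    ingroup_splits: frozenset


@dataclass
class MolecularReport:
    per_scheme: dict
    topologies_identical: bool
    seed: int
    n_bootstrap: int

    def focal_support_table(self) -> pd.DataFrame:
        rows = []
        for name, res in self.per_scheme.items():
            for clade, support in res.focal_supports.items():
                rows.append(
                    {
                        "scheme": name,
                        "clade": clade,
                        "support": support if support != "absent" else float("nan"),
                        "in_best_tree": support != "absent",
                    }
                )
        return pd.DataFrame(
            rows, columns=["scheme", "clade", "support", "in_best_tree"]
        )


def run_molecular_arm(
    aln: Union[Alignment, str, Path],
    schemes: Sequence[OutgroupScheme],
    n_bootstrap: int = 100,
    seed: int = 0,
    params_init: Optional[GTRIGParams] = None,
    focal_clades: Optional[dict] = None,
    estimate_params: bool = True,
    out_dir: Optional[Union[str, Path]] = None,
) -> MolecularReport:
    """Per outgroup scheme: subset -> fit model -> search -> bootstrap ->
    root -> focal-clade supports; then compare ingroup topologies."""
    if not isinstance(aln, Alignment):
        aln = read_fasta(aln)
    if not schemes:
        raise ValueError("at least one outgroup scheme is required")
    if focal_clades is None:
        focal_clades = DEFAULT_FOCAL_CLADES
    if params_init is None:
        params_init = GTRIGParams()

    results: dict[str, SchemeResult] = {}
    for idx, scheme in enumerate(schemes):
        missing = [t for t in scheme.taxa if t not in aln.taxon_ids]
        if missing:
            raise ValueError(
                f"scheme {scheme.name!r} taxa missing from alignment: {missing}"
            )
        sub = aln.subset(scheme.taxa)
        if estimate_params:
            start = nj_tree(pairwise_distances(sub))
            for node in start.postorder():
                if node is not start.root and (node.length is None or node.length <= 0):
                    node.length = 1e-6
            params = estimate_model_params(start, sub, params_init)
        else:
            params = params_init
        scheme_seed = seed + 7919 * idx
        summary = bootstrap_support(sub, params, n_bootstrap, scheme_seed)
        rooted = root_with_outgroup(summary.best_tree, scheme)
        focal = {
            name: clade_support(summary, taxa)
            for name, taxa in focal_clades.items()
            if set(taxa) <= set(scheme.taxa)
        }
        ingroup_tree = summary.best_tree.prune_to(scheme.ingroup)
        results[scheme.name] = SchemeResult(
            scheme=scheme,
            params=params,
            summary=summary,
            rooted_tree=rooted,
            newick=serialize_newick(rooted),
            focal_supports=focal,
            ingroup_splits=frozenset(ingroup_tree.bipartitions()),
        )

    splits = [r.ingroup_splits for r in results.values()]
    identical = all(s == splits[0] for s in splits)
    report = MolecularReport(
        per_scheme=results,
        topologies_identical=identical,
        seed=seed,
        n_bootstrap=n_bootstrap,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            safe = name.replace(" ", "_").lower()
            (out / f"tree_{safe}.nwk").write_text(res.newick + "\n")
            rows = [
                {
                    "clade_members": ";".join(sorted(split)),
                    "support": frac,
                    "in_best_tree": True,
                }
                for split, frac in sorted(
                    res.summary.support.items(),
                    key=lambda kv: (-kv[1], sorted(kv[0])),
                )
            ]
            pd.DataFrame(
                rows, columns=["clade_members", "support", "in_best_tree"]
            ).to_csv(out / f"supports_{safe}.csv", index=False)
        report.focal_support_table().to_csv(
            out / "focal_clade_supports.csv", index=False
        )
        meta = {
            "seed": seed,
            "n_bootstrap": n_bootstrap,
            "topologies_identical_across_schemes": identical,
            "schemes": [s.name for s in schemes],
            "tolerances": {"branch_length": 1e-6, "model_loglik": 1e-5},
        }
        with open(out / "run_log.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return report
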