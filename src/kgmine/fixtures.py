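"""Synthetic and transcribed fixture bundles for every pipeline stage.

Two kinds of fixture live here:

* **Synthetic tables** with known ground truth: a seeded generator writes a
  supplementary-style TSV, its transform config, and a resolver, and
  computes the expected assertions with an independent straightforward
  row-walk that shares no code with the transform engine — so end-to-end
  pipeline equality can be checked exactly.

* **Case-study bundles** transcribing the worked microbiome examples: the
  helminthiasis/NAFLD edge set (two tables: a helminth–microbiota
  association study and a Mendelian-randomization study of gut taxa and
  liver disease) and the ten *Alistipes* edges (short-chain fatty acids,
  tryptophan, 3-formylindole, and five inflammation-related mouse genes).
  All numeric attribute values are transcribed from numbers printed in the
  source narrative; values printed as upper bounds keep the bound value
  with a qualifier note. Only the two MONDO disease CURIEs are printed in
  that narrative — the remaining resolver CURIEs here are illustrative
  local-resolver content.

Nothing in this module touches the network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .scorer import EdgeFeatureRecord

# ---------------------------------------------------------------------------
# Synthetic supplementary tables


@dataclass
class SyntheticSpec:
    """Generation recipe for one synthetic supplementary table.

    P-values follow the study-condition mixture: a fraction ``f_sig`` drawn
    from Uniform(0, 0.05) (clearly significant) and the rest from
    Uniform(0.05, 1). Effect sizes are Normal(0, sigma). A fraction of
    subject labels is deliberately absent from the resolver to exercise the
    drop-on-failure rule.
    """

    seed: int = 0
    n_rows: int = 50
    f_sig: float = 0.5
    effect_sigma: float = 0.5
    fraction_unmappable: float = 0.1
    fraction_null_effect: float = 0.1
    fraction_duplicate: float = 0.1
    n_taxa: int = 20
    n_diseases: int = 5
    predicate: str = "biolink:affects"
    subject_category: str = "biolink:OrganismTaxon"
    object_category: str = "biolink:Disease"
    publication_id: str = "synthetic_pub"
    p_cutoff: float = 0.1

    def validate(self) -> None:
        for name in ("f_sig", "fraction_unmappable", "fraction_null_effect",
                     "fraction_duplicate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


_TESTS = ["wilcoxon", "spearman", "wald", "ivw", "zigmm"]


def _clean(label: str) -> str:
    # deliberately re-stated here: the oracle must not share transform code
    return " ".join(label.replace("_", " ").split()).lower()


def generate_synthetic_table(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Any]:
    """Write table.tsv + config.yaml + resolver.tsv; return paths and oracle.

    The returned ``expected_assertions`` are computed by a direct row-walk
    over the in-memory raw rows (clean labels, exponentiate the stored
    log10 p, drop null effects, first-wins dedup, p < cutoff), independent
    of the transform engine. ``expected_dropped`` counts survivors whose
    subject label is unmappable.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    taxa = [f"Taxon_{i:03d}" for i in range(spec.n_taxa)]
    diseases = [f"Disease_{j}" for j in range(spec.n_diseases)]
    n_unmappable = int(round(spec.fraction_unmappable * spec.n_taxa))
    unmappable = set(taxa[:n_unmappable])  # deterministic choice

    raw_rows: list[dict[str, Any]] = []
    for _ in range(spec.n_rows):
        if raw_rows and rng.random() < spec.fraction_duplicate:
            raw_rows.append(dict(raw_rows[int(rng.integers(len(raw_rows)))]))
            continue
        p = (
            rng.uniform(0.0, 0.05) if rng.random() < spec.f_sig
            else rng.uniform(0.05, 1.0)
        )
        p = max(p, 1e-300)
        effect = (
            None if rng.random() < spec.fraction_null_effect
            else float(rng.normal(0.0, spec.effect_sigma))
        )
        raw_rows.append(
            {
                "taxon": taxa[int(rng.integers(spec.n_taxa))],
                "disease": diseases[int(rng.integers(spec.n_diseases))],
                "log10_p": float(math.log10(p)),
                "effect": effect,
                "test": _TESTS[int(rng.integers(len(_TESTS)))],
            }
        )

    table_path = out_dir / "table.tsv"
    with open(table_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("taxon\tdisease\tlog10_p\teffect\ttest\n")
        for r in raw_rows:
            eff = "" if r["effect"] is None else repr(r["effect"])
            fh.write(
                f"{r['taxon']}\t{r['disease']}\t{r['log10_p']!r}\t{eff}\t{r['test']}\n"
            )

    config = {
        "table_locator": {"path": str(table_path), "format": "tsv", "header_row": 0},
        "ops": [
            {"kind": "text_clean", "input_column": "taxon",
             "output_column": "taxon_clean",
             "rules": ["underscore_to_space", "collapse_whitespace", "lowercase"]},
            {"kind": "text_clean", "input_column": "disease",
             "output_column": "disease_clean",
             "rules": ["underscore_to_space", "collapse_whitespace", "lowercase"]},
            {"kind": "exponentiate", "input_column": "log10_p",
             "output_column": "p", "base": 10},
            {"kind": "drop_nulls", "subset": ["effect"]},
            {"kind": "drop_duplicates", "subset": ["taxon", "disease"]},
        ],
        "role_map": {
            "subject": "taxon_clean",
            "object": "disease_clean",
            "predicate": spec.predicate,
            "subject_category": spec.subject_category,
            "object_category": spec.object_category,
        },
        "attribute_map": {
            "p_value": "p", "effect_size": "effect", "statistical_test": "test",
        },
        "constants": {"publication_id": spec.publication_id},
        "p_cutoff": spec.p_cutoff,
    }
    config_path = out_dir / "config.yaml"
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    resolver_path = out_dir / "resolver.tsv"
    with open(resolver_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("label\tcategory_hint\tcurie\tname\tsource_db\n")
        for i, t in enumerate(taxa):
            if t in unmappable:
                continue
            fh.write(
                f"{_clean(t)}\t{spec.subject_category}\tTAX:{i:04d}\t{t}\tsynthetic_tax\n"
            )
        for j, d in enumerate(diseases):
            fh.write(
                f"{_clean(d)}\t{spec.object_category}\tDIS:{j:04d}\t{d}\tsynthetic_dis\n"
            )

    # --- independent row-walk oracle -------------------------------------
    survivors: list[dict[str, Any]] = []
    seen: set[tuple[str, str]] = set()
    for r in raw_rows:
        if r["effect"] is None:
            continue
        key = (r["taxon"], r["disease"])
        if key in seen:
            continue
        seen.add(key)
        p = 10.0 ** r["log10_p"]
        if not p < spec.p_cutoff:
            continue
        survivors.append(
            {
                "subject_label": _clean(r["taxon"]),
                "object_label": _clean(r["disease"]),
                "predicate": spec.predicate,
                "subject_category": spec.subject_category,
                "object_category": spec.object_category,
                "p_value": p,
                "effect_size": r["effect"],
                "statistical_test": r["test"],
                "unmappable": r["taxon"] in unmappable,
            }
        )

    return {
        "table_path": table_path,
        "config_path": config_path,
        "resolver_path": resolver_path,
        "expected_assertions": survivors,
        "expected_dropped": sum(1 for s in survivors if s["unmappable"]),
    }


# ---------------------------------------------------------------------------
# Case-study bundles (values transcribed from the source narrative)


@dataclass
class FixtureBundle:
    tables: dict[str, str]  # table_id -> TSV content
    configs: dict[str, dict]  # table_id -> config dict
    resolver_rows: list[tuple[str, str, str, str, str]]
    expected_edge_count: int
    captions: dict[str, str] = field(default_factory=dict)
    publication_ids: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Any]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table_paths, config_paths = {}, {}
        for tid, content in self.tables.items():
            tpath = out_dir / f"{tid}.tsv"
            tpath.write_text(content, encoding="utf-8")
            cfg = dict(self.configs[tid])
            cfg["table_locator"] = {
                "path": str(tpath), "format": "tsv", "header_row": 0,
            }
            cpath = out_dir / f"{tid}.yaml"
            with open(cpath, "w", encoding="utf-8") as fh:
                yaml.safe_dump(cfg, fh, sort_keys=False)
            table_paths[tid] = tpath
            config_paths[tid] = cpath
        rpath = out_dir / "resolver.tsv"
        with open(rpath, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("label\tcategory_hint\tcurie\tname\tsource_db\n")
            for row in self.resolver_rows:
                fh.write("\t".join(row) + "\n")
        manifest = out_dir / "manifest.json"
        manifest.write_text(
            json.dumps(
                {"expected_edge_count": self.expected_edge_count,
                 "tables": sorted(self.tables)},
                indent=2,
            ),
            encoding="utf-8",
        )
        return {
            "tables": table_paths,
            "configs": config_paths,
            "resolver": rpath,
            "expected_edge_count": self.expected_edge_count,
        }


_TAXON = "biolink:OrganismTaxon"
_DISEASE = "biolink:Disease"
_SMALL_MOL = "biolink:SmallMolecule"
_GENE = "biolink:Gene"


def _cs1_bundle() -> FixtureBundle:
    # Helminth infection vs. gut taxa: B-H adjusted p-values; the
    # Lactobacillales value is printed as ~0 and stored as 1e-12.
    helminth_tsv = (
        "disease\torder\tadjusted_p\n"
        "helminthiasis\tBurkholderiales\t0.0026\n"
        "helminthiasis\tLactobacillales\t1e-12\n"
    )
    helminth_cfg = {
        "ops": [],
        "role_map": {
            "subject": "disease", "object": "order",
            "predicate": "biolink:associated_with",
            "subject_category": _DISEASE, "object_category": _TAXON,
        },
        "attribute_map": {"adjusted_p": "adjusted_p"},
        "constants": {
            "publication_id": "pub_helminth_microbiota",
            "correction_method": "benjamini_hochberg",
            "notes": "Lactobacillales adjusted p printed as ~0; stored as 1e-12",
        },
        "p_cutoff": 0.1,
    }
    # Mendelian randomization of gut taxa on liver disease: all four
    # adjusted p-values are printed upper bounds ("<x").
    mr_tsv = (
        "taxon\tdisease\tadjusted_p\ttest\n"
        "Betaproteobacteria\tNAFLD\t0.0218\tIVW\n"
        "Betaproteobacteria\tNAFLD\t0.000076\tIVW radial\n"
        "Burkholderiales\tNAFLD\t0.075\t\n"
        "Lactobacillus\tNAFLD\t0.0664\t\n"
    )
    mr_cfg = {
        "ops": [],
        "role_map": {
            "subject": "taxon", "object": "disease",
            "predicate": "biolink:affects",
            "subject_category": _TAXON, "object_category": _DISEASE,
        },
        "attribute_map": {"adjusted_p": "adjusted_p", "statistical_test": "test"},
        "constants": {
            "publication_id": "pub_mr_gut_liver",
            "correction_method": "benjamini_hochberg",
            "notes": "adjusted p-values are printed upper bounds",
        },
        "p_cutoff": 0.1,
    }
    resolver = [
        ("helminthiasis", _DISEASE, "MONDO:0004664", "helminthiasis", "mondo"),
        ("nafld", _DISEASE, "MONDO:0013209",
         "metabolic dysfunction-associated steatotic liver disease", "mondo"),
        ("burkholderiales", _TAXON, "NCBITaxon:80840", "Burkholderiales",
         "ncbi_taxonomy"),
        ("lactobacillales", _TAXON, "NCBITaxon:186826", "Lactobacillales",
         "ncbi_taxonomy"),
        ("betaproteobacteria", _TAXON, "NCBITaxon:28216", "Betaproteobacteria",
         "ncbi_taxonomy"),
        ("lactobacillus", _TAXON, "NCBITaxon:1578", "Lactobacillus",
         "ncbi_taxonomy"),
    ]
    return FixtureBundle(
        tables={"cs1_helminth": helminth_tsv, "cs1_mr": mr_tsv},
        configs={"cs1_helminth": helminth_cfg, "cs1_mr": mr_cfg},
        resolver_rows=resolver,
        expected_edge_count=6,
    )


def _cs2_bundle() -> FixtureBundle:
    # Infant gut microbiome vs. host metabolome: Spearman correlations with
    # B-H adjusted p-values; Alistipes negatively correlates with three
    # short-chain fatty acids and tryptophan.
    metab_tsv = (
        "genus\tmetabolite\trho\tadjusted_p\n"
        "g__Alistipes\tbutyric acid\t-0.31\t0.002\n"
        "g__Alistipes\tpropanoic acid\t-0.366\t0.001\n"
        "g__Alistipes\tacetate\t-0.225\t0.032\n"
        "g__Alistipes\ttryptophan\t-0.28\t0.005\n"
    )
    metab_cfg = {
        "ops": [
            {"kind": "text_clean", "input_column": "genus",
             "output_column": "genus_clean",
             "rules": ["strip_rank_prefix", "underscore_to_space",
                       "collapse_whitespace", "lowercase"]},
        ],
        "role_map": {
            "subject": "genus_clean", "object": "metabolite",
            "predicate": "biolink:correlated_with",
            "subject_category": _TAXON, "object_category": _SMALL_MOL,
        },
        "attribute_map": {"effect_size": "rho", "adjusted_p": "adjusted_p"},
        "constants": {
            "publication_id": "pub_infant_metabolome",
            "correction_method": "benjamini_hochberg",
            "effect_metric": "spearman_correlation",
            "statistical_test": "spearman",
        },
        "p_cutoff": 0.1,
    }
    # Joint genetics/microbiome/metabolome study: a weak positive
    # association with 3-formylindole (two-sided Wald estimate 0.018,
    # Bonferroni adjusted p 0.0032).
    mbqtl_tsv = (
        "genus\tmetabolite\testimate\tadjusted_p\n"
        "Alistipes\t3-formylindole\t0.018\t0.0032\n"
    )
    mbqtl_cfg = {
        "ops": [],
        "role_map": {
            "subject": "genus", "object": "metabolite",
            "predicate": "biolink:correlated_with",
            "subject_category": _TAXON, "object_category": _SMALL_MOL,
        },
        "attribute_map": {"effect_size": "estimate", "adjusted_p": "adjusted_p"},
        "constants": {
            "publication_id": "pub_genetics_metabolome",
            "correction_method": "bonferroni",
            "statistical_test": "two-sided Wald",
            "notes": "very weak effect size relative to the other associations",
        },
        "p_cutoff": 0.1,
    }
    # Mouse inflammaging study: correlation directions printed in the
    # narrative, numeric values only in an embedded figure table (not
    # transcribed), so these rows carry direction notes and no p-values.
    genes_tsv = (
        "genus\tgene\tdirection\n"
        "Alistipes\tSaa1\tpositively correlated\n"
        "Alistipes\tGhr\tpositively correlated\n"
        "Alistipes\tTnfrsf11a\tnegatively correlated\n"
        "Alistipes\tFcer1g\tnegatively correlated\n"
        "Alistipes\tAdora1\tnegatively correlated\n"
    )
    genes_cfg = {
        "ops": [],
        "role_map": {
            "subject": "genus", "object": "gene",
            "predicate": "biolink:correlated_with",
            "subject_category": _TAXON, "object_category": _GENE,
        },
        "attribute_map": {"notes": "direction"},
        "constants": {
            "publication_id": "pub_inflammaging",
            "effect_metric": "correlation_direction",
        },
        "p_cutoff": 0.1,
    }
    resolver = [
        ("alistipes", _TAXON, "NCBITaxon:239759", "Alistipes", "ncbi_taxonomy"),
        ("butyric acid", _SMALL_MOL, "CHEBI:30772", "butyric acid", "chebi"),
        ("propanoic acid", _SMALL_MOL, "CHEBI:30768", "propionic acid", "chebi"),
        ("acetate", _SMALL_MOL, "CHEBI:30089", "acetate", "chebi"),
        ("tryptophan", _SMALL_MOL, "CHEBI:16828", "tryptophan", "chebi"),
        ("3-formylindole", _SMALL_MOL, "CHEBI:28238", "indole-3-carbaldehyde",
         "chebi"),
        ("saa1", _GENE, "NCBIGene:20208", "Saa1", "ncbi_gene"),
        ("ghr", _GENE, "NCBIGene:14600", "Ghr", "ncbi_gene"),
        ("tnfrsf11a", _GENE, "NCBIGene:21934", "Tnfrsf11a", "ncbi_gene"),
        ("fcer1g", _GENE, "NCBIGene:14127", "Fcer1g", "ncbi_gene"),
        ("adora1", _GENE, "NCBIGene:11539", "Adora1", "ncbi_gene"),
    ]
    return FixtureBundle(
        tables={
            "cs2_metabolites": metab_tsv,
            "cs2_mbqtl": mbqtl_tsv,
            "cs2_genes": genes_tsv,
        },
        configs={
            "cs2_metabolites": metab_cfg,
            "cs2_mbqtl": mbqtl_cfg,
            "cs2_genes": genes_cfg,
        },
        resolver_rows=resolver,
        expected_edge_count=10,
    )


_CASE_STUDIES = {
    "cs1_helminth_nafld": _cs1_bundle,
    "cs2_alistipes": _cs2_bundle,
}


def case_study_fixture(name: str) -> FixtureBundle:
    """Return the named case-study bundle (``cs1_helminth_nafld`` or
    ``cs2_alistipes``); unknown names are a configuration failure."""
    try:
        return _CASE_STUDIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown case study {name!r}; known: {sorted(_CASE_STUDIES)}"
        ) from None


# ---------------------------------------------------------------------------
# Synthetic training sets for the edge scorer


_NLP_TYPES = ["none", "regex", "table_parse"]
_MAP_DBS = ["ncbi_taxonomy", "chebi", "mondo", "ncbi_gene"]
_CORRECTIONS = ["true", "false", "unknown"]


def default_rubric(
    record: EdgeFeatureRecord, rng: np.random.Generator, noise_sd: float = 2.0
) -> float:
    """Significance-linked manual-scoring stand-in on a 0–100 scale:
    100·(1 − governing p) + 10·[FDR-corrected] + Normal(0, noise), clipped
    at 0."""
    p = record.adjusted_p if record.adjusted_p is not None else record.p_value
    p = 1.0 if p is None else p
    label = 100.0 * (1.0 - p) + 10.0 * (record.fdr_corrected == "true")
    if noise_sd > 0:
        label += rng.normal(0.0, noise_sd)
    return max(label, 0.0)


def generate_scored_training_set(
    n: int, seed: int = 7, rubric=default_rubric
) -> tuple[list[EdgeFeatureRecord], list[float]]:
    """Generate ``n`` unique feature records with rubric-derived labels."""
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    records, labels = [], []
    for i in range(n):
        p = float(rng.uniform(1e-4, 1.0))
        has_adj = rng.random() < 0.7
        adj = float(min(1.0, p * rng.uniform(1.0, 3.0))) if has_adj else None
        fdr = _CORRECTIONS[int(rng.integers(3))] if has_adj else "unknown"
        records.append(
            EdgeFeatureRecord(
                p_value=p,
                adjusted_p=adj,
                sample_size=int(rng.integers(10, 2000)),
                fdr_corrected=fdr,
                effect_size=float(rng.normal(0.0, 0.5)),
                statistical_test=_TESTS[int(rng.integers(len(_TESTS)))],
                nlp_type=_NLP_TYPES[int(rng.integers(len(_NLP_TYPES)))],
                subject_map_db=_MAP_DBS[int(rng.integers(len(_MAP_DBS)))],
                object_map_db=_MAP_DBS[int(rng.integers(len(_MAP_DBS)))],
                notes=f"synthetic note {i}",  # index keeps combinations unique
                caption=f"synthetic caption {i % 17}",
            )
        )
        labels.append(float(rubric(records[-1], rng)))
    return records, labels
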