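"""Experiment configuration files.

An experiment is described in a small YAML document::

    perturbations:
      - gene: chico
        kind: heterozygous_knockout
    phenotype: long_lived        # long_lived | short_lived | unchanged
    threshold: 0.005             # adjusted-P cutoff
    de_table: de.tsv             # optional, path relative to the config
    columns:                     # optional column-name overrides
      gene: gene
      lfc: logFC
      p: adj.P.Val
    de_states:                   # optional explicit DE directions,
      Ilp2: up                   # merged over the table-derived calls

Either ``de_table`` or ``de_states`` (or both) may be present; explicit
``de_states`` entries override table-derived ones.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiments import (
    DEFAULT_DE_THRESHOLD,
    Direction,
    ExperimentFacts,
    FactsError,
    Perturbation,
    PerturbationKind,
    PhenotypeValue,
    build_facts,
    load_expression_table,
    select_de_genes,
)
from .model import PathwayGraph


class ConfigError(ValueError):
    """Raised on an unusable experiment configuration."""


def load_experiment_config(path: str | Path, graph: PathwayGraph) -> ExperimentFacts:
    """Read an experiment YAML file and build its fact base."""
    path = Path(path)
    try:
        document = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(document, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")

    raw_perturbations = document.get("perturbations") or []
    perturbations = []
    for entry in raw_perturbations:
        try:
            perturbations.append(
                Perturbation(
                    gene=str(entry["gene"]),
                    kind=PerturbationKind(entry["kind"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise ConfigError(f"{path}: bad perturbation entry {entry!r}") from exc

    phenotype_text = document.get("phenotype")
    try:
        phenotype = (
            PhenotypeValue(phenotype_text) if phenotype_text is not None else None
        )
    except ValueError as exc:
        raise ConfigError(
            f"{path}: unknown phenotype {phenotype_text!r}"
        ) from exc

    threshold = float(document.get("threshold", DEFAULT_DE_THRESHOLD))
    if not 0.0 < threshold <= 1.0:
        raise ConfigError(f"{path}: threshold must be in (0, 1]")

    de: dict[str, Direction] = {}
    table_name = document.get("de_table")
    if table_name:
        table_path = (path.parent / table_name).resolve()
        if not table_path.exists():
            raise ConfigError(f"{path}: DE table {table_path} does not exist")
        columns = document.get("columns") or {}
        with open(table_path) as handle:
            records = load_expression_table(
                handle,
                gene_column=columns.get("gene", "gene"),
                lfc_column=columns.get("lfc", "logFC"),
                p_column=columns.get("p", "adj.P.Val"),
            )
        de.update(select_de_genes(records, threshold=threshold))
    for gene, direction in (document.get("de_states") or {}).items():
        try:
            de[str(gene)] = Direction(direction)
        except ValueError as exc:
            raise ConfigError(
                f"{path}: unknown DE direction {direction!r} for {gene!r}"
            ) from exc

    try:
        return build_facts(
            graph, perturbations, de, phenotype, de_threshold=threshold
        )
    except FactsError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
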