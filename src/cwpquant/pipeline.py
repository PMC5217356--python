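"""End-to-end pipeline: observations + annotations -> reports.

Chains the quantification cascade, the cell-wall-protein selection, the
stage-effect statistics and the stage-partition reporting into one call
with a single configuration object. Each intermediate product stays
available on the returned :class:`PipelineResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import quantify as q
from . import report as rep
from . import select as sel
from . import stats as st
from .io import PipelineConfig

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    config: PipelineConfig
    peptide_abundances: pd.DataFrame
    protein_abundances: pd.DataFrame
    cwp_classes: pd.DataFrame          # accession, functional_class
    exclusions: pd.DataFrame           # accession, failed_rule
    matrix: pd.DataFrame               # imputed log10 CWP x lane matrix
    anova: pd.DataFrame
    clusters: st.ClusterAssignment | None
    pca: pd.DataFrame | None
    venn: rep.VennPartition | None
    class_dist: pd.DataFrame
    audit: q.FilterAudit = field(default_factory=q.FilterAudit)

    def report_tables(self) -> dict[str, pd.DataFrame]:
        """The report files, as name -> DataFrame."""
        tables = {
            "cwp_list": self.cwp_classes,
            "class_distribution": self.class_dist,
            "anova": self.anova.reset_index(),
            "protein_abundances": self.protein_abundances,
            "filter_audit": self.audit.to_frame(),
            "exclusions": self.exclusions,
        }
        if self.venn is not None:
            tables["venn_cells"] = self.venn.to_frame()
        if self.clusters is not None:
            tables["clusters"] = self.clusters.to_frame()
        else:
            tables["clusters"] = pd.DataFrame(
                columns=["accession", "cluster", "preferential_stages"])
        if self.pca is not None:
            tables["pca_lanes"] = self.pca.reset_index()
        return tables


def stage_membership(protein_abundances: pd.DataFrame) -> dict[str, frozenset]:
    """Stages at which each quantified protein was identified (>= 1 lane)."""
    if protein_abundances.empty:
        return {}
    grouped = protein_abundances.groupby("accession")["stage"].agg(set)
    return {acc: frozenset(s) for acc, s in grouped.items()}


def run_pipeline(observations: pd.DataFrame, annotations: pd.DataFrame,
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on an observation + annotation table pair."""
    config = config or PipelineConfig()
    config.validate()
    audit = q.FilterAudit()

    normalized = q.normalize_lanes(observations)
    peptides = q.aggregate_peptides(normalized, config, audit)
    peptides = q.filter_peptides(peptides, config, audit)
    proteins = q.quantify_proteins(peptides, config, audit)

    records = [sel.ProteinRecord.from_annotation_row(r)
               for r in annotations.itertuples(index=False)]
    cwps, exclusions = sel.select_cwps(records)
    cwp_classes = pd.DataFrame(
        [(r.accession, sel.classify_functional(r)) for r in cwps],
        columns=["accession", "functional_class"])

    # quantified CWPs only, from here on
    quantified_cwps = cwp_classes[
        cwp_classes["accession"].isin(proteins["accession"])]
    audit.record("restrict_to_cwps", proteins["accession"].nunique(),
                 len(quantified_cwps))
    prot_cwp = proteins[proteins["accession"].isin(
        quantified_cwps["accession"])]

    membership = stage_membership(prot_cwp)
    venn = None
    if len(config.stages) == 3:
        venn = rep.venn_partition(membership, config.stages)
    class_dist = rep.class_distribution(
        quantified_cwps.set_index("accession")["functional_class"])

    matrix = st.build_matrix(prot_cwp, config)
    matrix = st.impute_within_stage(matrix)
    anova = st.anova_stage_effect(matrix, config.p_threshold)

    pca = None
    try:
        pca = st.pca_lanes(matrix)
    except ValueError:
        pass

    clusters = None
    significant = anova.index[anova["significant"]]
    sig_matrix = matrix.loc[significant].dropna(axis=0)
    if len(sig_matrix) >= 2:
        clusters = st.cluster_and_cut(
            sig_matrix, config.cluster_cut,
            metric=config.distance, method=config.linkage)
        # the abundance margin rule discriminates on the linear scale;
        # on log10 values a 10% margin would span several fold changes
        st.preferential_stages(clusters, 10.0 ** sig_matrix,
                               margin=config.preferential_margin)

    return PipelineResult(
        config=config, peptide_abundances=peptides,
        protein_abundances=prot_cwp, cwp_classes=quantified_cwps,
        exclusions=exclusions, matrix=matrix, anova=anova,
        clusters=clusters, pca=pca, venn=venn, class_dist=class_dist,
        audit=audit)
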