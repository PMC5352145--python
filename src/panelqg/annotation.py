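"""Site-class annotation of associated polymorphisms and class enrichment.

A marker is genic if it falls in a gene model or within 1 kb (inclusive)
up/downstream of one.  When several features apply (overlapping genes), a
fixed precedence resolves the single reported class:

    non_synonymous > synonymous > exon_other > utr5 > utr3 > intron
    > downstream_1kb > upstream_1kb > intergenic

Synonymy calls need codon context (reference codon, position in codon,
strand) carried on the CDS interval; coding sites without context are
reported as ``exon_other``, never guessed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .io_formats import GeneModelSet

CLASS_PRECEDENCE = ["non_synonymous", "synonymous", "exon_other", "utr5",
                    "utr3", "intron", "downstream_1kb", "upstream_1kb",
                    "intergenic"]

FUNCTIONAL_CLASSES = ("intron", "utr5", "utr3", "non_synonymous")

# published composition of the D. melanogaster genome, overridable input
GENOME_COMPOSITION = {
    "genic": 0.482,
    "exonic": 0.183,
    "intronic": 0.30,
    "intergenic": 0.518,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SiteClassification:
    marker_id: str
    site_class: str
    gene_ids: list

    @property
    def genic(self) -> bool:
        return self.site_class != "intergenic"


def _coding_class(ref: str, alt: str, feature, strand: str) -> str:
    codon = feature["ref_codon"]
    codon_pos = feature["codon_pos"]
    if codon is None or codon_pos is None or pd.isna(codon) or pd.isna(codon_pos):
        warnings.warn("coding interval lacks codon context; class exon_other")
        return "exon_other"
    if len(ref) != 1 or len(alt) != 1:
        return "exon_other"  # indel in coding sequence; synonymy undefined
    codon = str(codon).upper()
    i = int(codon_pos) - 1
    r, a = ref.upper(), alt.upper()
    if strand == "-":
        r, a = r.translate(_COMPLEMENT), a.translate(_COMPLEMENT)
    if codon[i] != r:
        warnings.warn(f"reference allele {ref} does not match codon {codon} "
                      f"position {codon_pos}; class exon_other")
        return "exon_other"
    alt_codon = codon[:i] + a + codon[i + 1:]
    same = Seq(codon).translate() == Seq(alt_codon).translate()
    return "synonymous" if same else "non_synonymous"


def classify_site(chrom: str, pos: int, ref: str, alt: str,
                  gene_models: GeneModelSet,
                  flank: int = 1000) -> SiteClassification:
    """Classify one marker (``pos`` 1-based) against the gene models."""
    pos0 = pos - 1
    marker_id = f"{chrom}:{pos}:{ref}:{alt}"
    strands = gene_models.genes.set_index("gene_id")["strand"]

    candidates: list[str] = []
    gene_ids: set = set()

    inside = gene_models.genes_at(chrom, pos0)
    for _, g in inside.iterrows():
        gene_ids.add(g["gene_id"])
    feats = gene_models.features_at(chrom, pos0)
    for _, f in feats.iterrows():
        if f["type"] == "exon_cds":
            candidates.append(_coding_class(ref, alt, f,
                                            strands.get(f["gene_id"], "+")))
        elif f["type"] in ("utr5", "utr3", "intron"):
            candidates.append(f["type"])
        gene_ids.add(f["gene_id"])
    # inside a gene span but in none of its typed features: intron by gap rule
    for _, g in inside.iterrows():
        sub = feats[feats["gene_id"] == g["gene_id"]]
        if sub.empty:
            candidates.append("intron")

    if not candidates:  # flanking rule, strand-aware, 1 kb inclusive
        near = gene_models.genes_near(chrom, pos0, flank)
        for _, g in near.iterrows():
            if g["start"] <= pos0 < g["end"]:
                continue
            if pos0 >= g["end"]:
                dist = pos0 - (g["end"] - 1)
                side_downstream = g["strand"] != "-"
            else:
                dist = g["start"] - pos0
                side_downstream = g["strand"] == "-"
            if dist <= flank:
                candidates.append("downstream_1kb" if side_downstream
                                  else "upstream_1kb")
                gene_ids.add(g["gene_id"])

    if not candidates:
        return SiteClassification(marker_id, "intergenic", [])
    best = min(candidates, key=CLASS_PRECEDENCE.index)
    return SiteClassification(marker_id, best, sorted(gene_ids))


def classify_records(records: pd.DataFrame, gene_models: GeneModelSet,
                     flank: int = 1000) -> pd.DataFrame:
    """Classify every row of an association table (chrom,pos,ref,alt)."""
    rows = []
    for _, r in records.iterrows():
        c = classify_site(str(r["chrom"]), int(r["pos"]), r["ref"], r["alt"],
                          gene_models, flank)
        rows.append({"chrom": r["chrom"], "pos": r["pos"], "ref": r["ref"],
                     "alt": r["alt"], "class": c.site_class,
                     "genic": c.genic, "gene_ids": ";".join(c.gene_ids)})
    return pd.DataFrame(rows)


def enrichment_chisq(observed_in_class: int, total: int,
                     expected_proportion: float) -> dict:
    """Two-cell goodness-of-fit chi-square, 1 df, no continuity correction."""
    if not 0 <= observed_in_class <= total:
        raise ValueError("need 0 <= observed <= total")
    if not 0 < expected_proportion < 1:
        raise ValueError("expected proportion must be in (0, 1)")
    expected = np.array([expected_proportion * total,
                         (1 - expected_proportion) * total])
    observed = np.array([observed_in_class, total - observed_in_class])
    chi2, p = stats.chisquare(observed, expected)
    out = {"observed": int(observed_in_class), "total": int(total),
           "expected": float(expected[0]), "chi2": float(chi2), "df": 1,
           "p": float(p)}
    if expected.min() < 1:
        out["validity_warning"] = "expected cell below 1"
    return out


def class_inventory(classifications: pd.DataFrame) -> dict:
    """Counts per site class plus the functional and genic fractions.

    The functional fraction counts introns, UTRs and non-synonymous changes;
    the genic fraction is everything not intergenic (1-kb flanks count as
    genic).
    """
    if classifications.empty:
        raise ValueError("empty classification set")
    counts = classifications["class"].value_counts().to_dict()
    total = len(classifications)
    functional = sum(counts.get(c, 0) for c in FUNCTIONAL_CLASSES)
    genic = total - counts.get("intergenic", 0)
    return {
        "counts": counts,
        "total": total,
        "functional": functional,
        "functional_fraction": functional / total,
        "genic": genic,
        "genic_fraction": genic / total,
    }


def write_classifications(classifications: pd.DataFrame, path) -> None:
    classifications.to_csv(path, sep="\t", index=False, lineterminator="\n")
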