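"""Published survey tables bundled as reference inputs.

Printed summary tables from a comparative Illumina survey of the
repetitive fraction of 10 wild *Helianthus* (sunflower) species and one
subspecies.  Species are keyed by their acronyms: AGR (*H. agrestis*),
ANN (*H. annuus*), PFA (*H. petiolaris* ssp. *fallax*), PPE
(*H. petiolaris* ssp. *petiolaris*), POR (*H. porteri*), DIV
(*H. divaricatus*), GIG (*H. giganteus*), CAL (*H. californicus*), HIR
(*H. hirsutus*), LAE (*H. laevigatus*), TUB (*H. tuberosus*).

These values are inputs for the worked-example statistics (repetitive
fractions, lineage totals, Gypsy/Copia ratios, maximum percentage
variation); the genome-proportion matrix itself is measured data, not
something the desk-scale simulations reproduce.
"""

from __future__ import annotations

import pandas as pd

SPECIES = ["ANN", "PFA", "PPE", "DIV", "HIR", "TUB", "GIG", "CAL", "LAE", "POR", "AGR"]


def species_table() -> pd.DataFrame:
    """Species, section, habit, ploidy and relative genome size (4C absorbance)."""
    rows = [
        # acronym, section, habit, ploidy, 4C absorbance
        ("AGR", "Agrestis", "annual", 2, 64.963),
        ("ANN", "Helianthus", "annual", 2, 27.865),
        ("PFA", "Helianthus", "annual", 2, 23.181),
        ("PPE", "Helianthus", "annual", 2, 26.151),
        ("POR", "Divaricati", "annual", 2, 28.964),
        ("DIV", "Divaricati", "perennial", 2, 32.828),
        ("GIG", "Divaricati", "perennial", 2, 34.246),
        ("CAL", "Divaricati", "perennial", 4, 71.352),
        ("HIR", "Divaricati", "perennial", 4, 61.023),
        ("LAE", "Divaricati", "perennial", 4, 86.956),
        ("TUB", "Divaricati", "perennial", 6, 67.811),
    ]
    return pd.DataFrame(
        rows, columns=["species", "section", "habit", "ploidy", "genome_size_4c"]
    ).set_index("species")


def clustering_read_counts() -> pd.DataFrame:
    """Reads processed by the comparative clustering and reads in clusters."""
    rows = [
        ("AGR", 2, 1_000_000, 259_362, 218_464),
        ("ANN", 2, 1_000_000, 260_544, 196_995),
        ("PFA", 2, 1_000_000, 260_192, 191_401),
        ("PPE", 2, 1_000_000, 259_278, 198_005),
        ("POR", 2, 1_000_000, 260_872, 207_361),
        ("DIV", 2, 1_000_000, 259_756, 200_072),
        ("GIG", 2, 1_000_000, 261_508, 204_244),
        ("CAL", 4, 2_000_000, 520_754, 386_259),
        ("HIR", 4, 2_000_000, 519_636, 396_207),
        ("LAE", 4, 2_000_000, 521_176, 406_256),
        ("TUB", 6, 3_000_000, 781_686, 620_615),
    ]
    return pd.DataFrame(
        rows,
        columns=["species", "ploidy", "reads_used", "reads_processed", "reads_in_clusters"],
    ).set_index("species")


def lineage_cluster_summary() -> pd.DataFrame:
    """LTR-RE cluster counts and pooled read percentages per lineage."""
    rows = [
        ("Copia", "AleII", 4, 0.84),
        ("Copia", "Angela", 5, 0.66),
        ("Copia", "Bianca", 1, 0.13),
        ("Copia", "Maximus/SIRE", 32, 6.46),
        ("Copia", "TAR/Tork", 7, 0.51),
        ("Copia", "unknown", 7, 2.88),
        ("Gypsy", "Athila", 25, 3.18),
        ("Gypsy", "Chromovirus", 105, 35.29),
        ("Gypsy", "Ogre/Tat", 20, 4.03),
        ("Gypsy", "unknown", 14, 3.15),
    ]
    return pd.DataFrame(
        rows, columns=["superfamily", "lineage", "n_clusters", "percent_of_reads"]
    )


def lineage_genome_proportions() -> pd.DataFrame:
    """Genome proportion (percent) of each LTR-RE lineage per species.

    Rows are (superfamily, lineage); columns are species acronyms.  The
    "unclassified" row holds LTR-RE clusters assignable to neither
    superfamily.
    """
    data = {
        #                      ANN    PFA    PPE    DIV    HIR    TUB    GIG    CAL    LAE    POR    AGR
        ("Copia", "AleII"): [0.89, 0.85, 0.75, 0.59, 0.82, 0.75, 0.82, 1.32, 0.66, 1.07, 0.57],
        ("Copia", "Angela"): [0.79, 0.82, 0.59, 0.57, 0.90, 0.71, 0.93, 0.46, 0.67, 0.45, 0.29],
        ("Copia", "Bianca"): [0.19, 0.21, 0.11, 0.14, 0.18, 0.12, 0.17, 0.07, 0.11, 0.11, 0.03],
        ("Copia", "Maximus/SIRE"): [6.72, 7.08, 7.21, 4.31, 6.11, 6.04, 6.40, 4.41, 4.90, 15.56, 7.08],
        ("Copia", "TAR/Tork"): [0.41, 0.49, 0.58, 0.59, 0.48, 0.52, 0.47, 0.32, 0.62, 0.63, 0.62],
        ("Copia", "unknown"): [3.43, 2.93, 2.83, 2.11, 3.09, 2.84, 3.02, 2.76, 2.28, 4.97, 2.04],
        ("Gypsy", "Athila"): [2.81, 3.00, 3.88, 3.29, 2.64, 3.29, 2.51, 2.87, 3.65, 4.07, 3.19],
        ("Gypsy", "Chromovirus"): [30.82, 29.92, 31.52, 37.85, 34.10, 36.87, 36.73, 33.83, 37.02, 25.25, 52.18],
        ("Gypsy", "Ogre/Tat"): [5.96, 3.98, 4.64, 3.76, 4.85, 5.22, 4.42, 2.83, 3.93, 1.78, 1.02],
        ("Gypsy", "unknown"): [2.75, 3.13, 4.11, 4.25, 2.85, 3.50, 2.36, 3.91, 3.59, 1.95, 0.64],
        ("unclassified", "unclassified"): [6.00, 5.93, 5.51, 5.40, 5.40, 5.31, 5.66, 5.97, 5.49, 5.98, 7.34],
    }
    df = pd.DataFrame(data, index=SPECIES).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["superfamily", "lineage"])
    return df


def published_summary_rows() -> pd.DataFrame:
    """Printed per-species superfamily totals and Gypsy/Copia ratios."""
    data = {
        "copia_total": [12.44, 12.39, 12.08, 8.31, 11.58, 10.98, 11.81, 9.34, 9.23, 22.79, 10.62],
        "gypsy_total": [42.34, 40.04, 44.14, 49.15, 44.44, 48.88, 46.02, 43.44, 48.18, 33.05, 57.03],
        "ltr_unclassified": [6.00, 5.93, 5.51, 5.40, 5.40, 5.31, 5.66, 5.97, 5.49, 5.98, 7.34],
        "annotated_ltr_total": [60.77, 58.36, 61.73, 62.86, 61.42, 65.18, 63.49, 58.75, 62.90, 61.83, 74.99],
        "gypsy_copia_ratio": [3.40, 3.23, 3.66, 5.91, 3.84, 4.45, 3.90, 4.65, 5.22, 1.45, 5.37],
    }
    return pd.DataFrame(data, index=SPECIES)
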