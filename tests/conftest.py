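import pandas as pd
import pytest

import intronseq as iq


@pytest.fixture(scope="session")
def small_config():
    return iq.SimulationConfig(n_genes=120, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """A parsed synthetic genome with catalog, counts and truth."""
    gff3, truth = iq.simulate_annotation(small_config)
    genes = iq.parse_gene_models(gff3)
    catalog = iq.build_feature_catalog(genes)
    exon_tab, intron_tab, truth = iq.simulate_counts(small_config, catalog, truth)
    return {
        "gff3": gff3,
        "genes": genes,
        "catalog": catalog,
        "exon": exon_tab,
        "intron": intron_tab,
        "truth": truth,
        "design": iq.make_design(small_config),
    }


def make_de_table(rows: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """DE table from {gene_id: (log2_fc, p_adjusted)}; all genes tested."""
    table = pd.DataFrame(
        {
            "log2_fc": {g: v[0] for g, v in rows.items()},
            "p_adjusted": {g: v[1] for g, v in rows.items()},
        }
    )
    table["p_value"] = table["p_adjusted"]
    table["base_mean"] = 100.0
    table["tested"] = True
    table.index.name = "gene_id"
    return table
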