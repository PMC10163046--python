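import numpy as np
import pandas as pd
import pytest

from ncplink import RelationshipTable, load_catalog

# Per-NCP values for two worked example rows (printed source data used as
# test input; totals are recomputed, never asserted from these dicts).
SALIX_ALBA = {
    "potential_crop": 1, "solid_wood": 1, "burned_wood": 1, "wild_food": 0,
    "wild_use": 1, "mellifera": 1, "forage_pasture": 1,
    "iconic_species": 1, "scientific_interest": 1, "endangered_habitat": 0,
    "decontamination": 1, "riverbank_erosion": 1, "hedge_crop_yield": 0,
    "reduce_runoff": 0, "keystone_species": 1, "reduce_landslide": 1,
}
CANIS_LUPUS = {
    "wild_food": 0, "wild_use": 0,
    "iconic_species": 1, "scientific_interest": 1, "endangered_habitat": 0,
    "riverbank_erosion": 0, "reduce_species_damage": -1,
    "keystone_species": 1, "reduce_landslide": 1,
}


@pytest.fixture(scope="session")
def catalog():
    return load_catalog("builtin")


def build_table(catalog, rows):
    """Construct a RelationshipTable from {species_id: (meta dict, cells dict)}.

    ``cells`` maps ncp_id -> value; applicable NCPs not mentioned stay
    NA_no_info.
    """
    meta_rows, cell_rows, index = [], [], []
    for sid, (meta, cells) in rows.items():
        meta = {"species_id": sid, "n_occurrences": 100, "alien": False,
                **meta}
        meta_rows.append(meta)
        row = {c: np.nan for c in catalog.ncp_ids}
        row.update(cells)
        cell_rows.append(row)
        index.append(sid)
    species = pd.DataFrame(meta_rows)
    cells = pd.DataFrame(cell_rows, index=index, columns=catalog.ncp_ids,
                         dtype=float)
    return RelationshipTable(catalog, species, cells)


@pytest.fixture
def table_builder(catalog):
    def _build(rows):
        return build_table(catalog, rows)
    return _build


@pytest.fixture
def salix_wolf_table(table_builder):
    return table_builder({
        "salix_alba": ({"lineage": "tracheophyte", "subgroup": "angiosperm",
                        "scientific_name": "Salix alba"}, SALIX_ALBA),
        "canis_lupus": ({"lineage": "vertebrate", "subgroup": "mammal",
                         "scientific_name": "Canis lupus"}, CANIS_LUPUS),
    })
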