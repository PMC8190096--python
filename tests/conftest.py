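import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from guildnet import SimDesign, generate_counts, generate_guild_db

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_design():
    """A shrunken NutNet-like design for fast integration tests."""
    return SimDesign(
        n_sites=6,
        n_genera={"AMF": 5, "PATHOGEN": 10, "SAPROTROPH": 10, "OTHER": 20},
        corr_blocks=np.eye(45),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_design):
    db, taxonomy = generate_guild_db(small_design)
    counts, meta, truth = generate_counts(small_design)
    return {"db": db, "taxonomy": taxonomy, "counts": counts, "meta": meta, "truth": truth}


@pytest.fixture()
def toy_db():
    """Hand-built guild database exercising every classification rule."""
    from guildnet import GuildDatabase

    records = pd.DataFrame(
        [
            ("Glomus", "genus", "Symbiotroph", "Arbuscular Mycorrhizal", "Highly Probable"),
            ("Rhizophagus", "genus", "Symbiotroph", "Arbuscular Mycorrhizal", "Possible"),
            ("Fusarium", "genus", "Pathotroph", "Plant Pathogen", "Probable"),
            ("Mortierella", "genus", "Saprotroph", "Soil Saprotroph", "Probable"),
            ("Coprinus", "genus", "Saprotroph", "Undefined Saprotroph", "Possible"),
            ("Trametes", "genus", "Saprotroph", "Wood Saprotroph", "Highly Probable"),
            ("Nectriaceae", "family", "Pathotroph", "Plant Pathogen", "Possible"),
            ("Alternaria", "genus", "Pathotroph",
             "Plant Pathogen|Undefined Saprotroph", "Probable"),
        ],
        columns=["taxon", "taxonomicLevel", "trophicMode", "guild", "confidenceRanking"],
    )
    return GuildDatabase(records)
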