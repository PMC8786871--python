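import io

import numpy as np
import pytest

from paleorates.fossil_records import read_occurrence_table

# a small hand-written occurrence table exercising qualifiers, ranks,
# duplicate specimens, and a wide dating window
TOY_CSV = """taxon,rank,qualifier,min_age,max_age,locality,stratum,specimen_id,clade
Cladosictis patagonica,species,,15.0,17.5,Santa Cruz,A,SC-1,Sparassodonta
Cladosictis cf. patagonica,species,,15.0,17.5,Santa Cruz,A,SC-2,Sparassodonta
Sipalocyon aff. gracilis,species,,14.0,18.0,Santa Cruz,B,SC-3,Sparassodonta
Borhyaena ? tuberata,species,,10.0,26.0,Pampa,A,PA-1,Sparassodonta
Thylacosmilus atrox,species,,3.0,9.0,Pampa,B,PA-2,Sparassodonta
Thylacosmilus atrox,species,,3.0,9.0,Pampa,B,PA-3,Sparassodonta
Borhyaena,genus,,12.0,12.0,Pampa,A,PA-4,Sparassodonta
"""


@pytest.fixture
def toy_table():
    return read_occurrence_table(io.StringIO(TOY_CSV))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
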