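from pathlib import Path

import pytest

from patternscore import fixtures, pattern_engine


@pytest.fixture
def compound_csv(tmp_path: Path) -> Path:
    path = tmp_path / "compounds.csv"
    path.write_text(
        "id,smiles,class\n"
        "X1,c1ccccc1,arenes\n"
        "X2,CCO,alcohols\n"
        "X3,CC(=O)Nc1ccccc1,amides\n"
    )
    return path


@pytest.fixture
def catalog_csv(tmp_path: Path) -> Path:
    path = tmp_path / "catalog.csv"
    path.write_text(
        "substructure_id,name,smiles\n"
        "S1,benzene,c1ccccc1\n"
        "S2,para-H phenol,Oc1ccc([H])cc1\n"
        "S3,dimethyl amine,CNC\n"
    )
    return path


@pytest.fixture(scope="session")
def demo_set():
    """One shared instance of the study-shaped synthetic dataset."""
    spec = fixtures.demo_spec(seed=7)
    records, truth, pattern_ids = fixtures.generate_compound_set(spec)
    return spec, records, truth, pattern_ids


@pytest.fixture(scope="session")
def demo_matrix(demo_set):
    spec, records, truth, pattern_ids = demo_set
    queries = [pattern_engine.compile_pattern(r) for r in fixtures.demo_catalog(spec)]
    return pattern_engine.occurrence_matrix(records, queries), queries
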