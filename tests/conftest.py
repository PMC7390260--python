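import numpy as np
import pytest

from omicslink import parse_knowledgebase


def write_kb_files(
    tmp_path,
    met2pathway: list[tuple] = (),
    pathway2gene: list[tuple] = (),
    ontology: list[tuple] = (),
    interactions: list[tuple] = (),
):
    """Write snapshot files from row tuples; returns the four paths."""
    paths = {}
    for name, rows in (
        ("met2pathway", met2pathway),
        ("pathway2gene", pathway2gene),
        ("ontology", ontology),
        ("interactions", interactions),
    ):
        path = tmp_path / f"{name}.tsv"
        path.write_text(
            "".join("\t".join(str(v) for v in row) + "\n" for row in rows),
            encoding="utf-8",
        )
        paths[name] = str(path)
    return paths


@pytest.fixture
def kb_factory(tmp_path):
    def build(**kwargs):
        paths = write_kb_files(tmp_path, **kwargs)
        return parse_knowledgebase(
            paths["met2pathway"],
            paths["pathway2gene"],
            paths["ontology"],
            paths["interactions"],
        )

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
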