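import numpy as np
import pytest

from plaidoh import fixtures, pipeline


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline run on the planted demo dataset, shared across
    tests that only read the result."""
    root = tmp_path_factory.mktemp("demo")
    spec = fixtures.demo_spec(seed=7)
    manifest = fixtures.generate_fixture(spec, root / "data")
    config = pipeline.RunConfig(
        input_path=manifest["input"],
        tracks=manifest["tracks"],
        outdir=str(root / "out"),
        seed=7,
    )
    result = pipeline.run_pipeline(config)
    return spec, manifest, config, result


def write_expression(path, rows, n_samples=2, header=None):
    """Small helper: write a bed-like expression table from tuples
    (chrom, start, stop, name, ttype, *expr)."""
    samples = header or [f"S{i + 1}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write("#CHR\tSTART\tSTOP\tNAME\tTYPE\t" + "\t".join(samples) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path
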