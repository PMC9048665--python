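from pathlib import Path

import pytest

from rvescore.rubric import Criterion, Rubric, ThresholdRule
from rvescore.variant import VariantSpec


def make_criterion(cid, component, weight, mode="manual", operator=None, cutoff=None,
                   source_key=None, description=""):
    rule = None
    if mode == "auto":
        rule = ThresholdRule(operator=operator, cutoff=cutoff, source_key=source_key)
    return Criterion(id=cid, component=component, description=description,
                     weight=weight, mode=mode, rule=rule)


@pytest.fixture
def toy_rubric():
    """Small 4-criterion rubric: clinical weights {2, 1}, functional {3, 1}."""
    return Rubric(
        criteria=(
            make_criterion("C1.1", "clinical", 2, mode="auto",
                           operator="lt", cutoff=0.01, source_key="gnomad_af"),
            make_criterion("C2.1", "clinical", 1),
            make_criterion("F1.1", "functional", 3, mode="auto",
                           operator="ge", cutoff=2.0, source_key="phylop"),
            make_criterion("F2.1", "functional", 1),
        ),
        version="toy-1",
    )


@pytest.fixture
def snv():
    return VariantSpec(assembly="GRCh38", chrom="chr1", pos=100, ref="G", alt="A",
                       gene="GENE1")


@pytest.fixture
def fixture_bundle_dir(tmp_path_factory):
    """Default-rubric all-pass bundle, generated once per test session."""
    from rvescore.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("bundle_allpass")
    return make_fixtures(1, "all-pass", out)


@pytest.fixture
def nocov_bundle_dir(tmp_path_factory):
    from rvescore.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("bundle_nocov")
    return make_fixtures(1, "no-coverage", out)
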