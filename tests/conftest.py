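import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from faerspv.faers_io import CaseReport, DrugMention, parse_partial_date
from faerspv.pipeline import RunConfig, run_pipeline
from faerspv.synthetic import SyntheticConfig, generate_bundle


def make_report(
    primaryid="1230001",
    caseid="123",
    drugs=(),
    reaction_pts=(),
    event_date=None,
    start_date=None,
    **kwargs,
):
    """Small builder for hand-written case-report fixtures."""
    mentions = []
    for spec in drugs:
        if isinstance(spec, DrugMention):
            mentions.append(spec)
        else:
            name, role = spec[0], spec[1]
            indication = spec[2] if len(spec) > 2 else None
            mentions.append(DrugMention(name=name, role=role, indication_pt=indication))
    if start_date is not None:
        start = parse_partial_date(start_date)
        for m in mentions:
            m.therapy_start = start
    return CaseReport(
        primaryid=primaryid,
        caseid=caseid,
        drugs=mentions,
        reaction_pts=list(reaction_pts),
        event_date=parse_partial_date(event_date) if event_date else None,
        **kwargs,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Default-conditions synthetic bundle, generated once per session."""
    out = tmp_path_factory.mktemp("bundle")
    config = SyntheticConfig(seed=20231)
    paths, truth = generate_bundle(config, out)
    return out, config, truth


@pytest.fixture(scope="session")
def pipeline_results(default_bundle, tmp_path_factory):
    """Full pipeline run over the default synthetic bundle."""
    bundle_dir, config, truth = default_bundle
    out = tmp_path_factory.mktemp("run")
    results = run_pipeline(
        RunConfig(input_dir=str(bundle_dir), output_dir=str(out), seed=config.seed)
    )
    return results, out, truth
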