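import pytest

from dielmet import linkage, quantify, rhythm, synthetic


@pytest.fixture(scope="session")
def design():
    return synthetic.StudyDesign()


@pytest.fixture(scope="session")
def one_period_design():
    return synthetic.StudyDesign(n_days_per_period=(4,))


@pytest.fixture(scope="session")
def emulation_study():
    """Study emulating the field campaign: 79 compounds, 55 diel,
    fold changes 1.6-12.8, peaks near 14:00/18:00, noise_cv 0.15."""
    design = synthetic.StudyDesign()
    compounds = synthetic.default_compounds(79, seed=11)
    truths = synthetic.default_truths(compounds, n_diel=55, noise_cv=0.15, seed=11)
    links = linkage.default_links()
    tr_truths = synthetic.default_transcript_truths(links, truths, lag_hours=4.0, seed=11)
    model = synthetic.MeasurementModel(is_injection_cv=0.1, matrix_suppression=0.8)
    return synthetic.simulate_study(
        design, truths, model, seed=11, compounds=compounds, transcript_truths=tr_truths
    )


@pytest.fixture(scope="session")
def emulation_concentrations(emulation_study):
    study = emulation_study
    spikes = dict(
        zip(study.is_spikes["internal_standard"], study.is_spikes["spike_pmol"])
    )
    return quantify.quantify_study(
        study.areas,
        study.is_areas,
        study.samples,
        study.compound_info(),
        spikes,
        additions=study.additions,
        external_standards=study.external_standards,
    )


@pytest.fixture(scope="session")
def emulation_rhythm(emulation_study, emulation_concentrations):
    values = emulation_concentrations.rename(
        columns={"compound": "signal_id", "pmol_per_L": "value"}
    )[["signal_id", "sample_id", "value"]]
    return rhythm.classify_signals(values, emulation_study.samples, scopes=["1"])
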