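"""Desk-scale benchmark profile for the synthetic Model A/B/C experiment.

The generator's defaults mirror the full study corpora (150 repetitions
per word, 100 per sentence); a full-size contrastive training run at those
counts is hours of CPU work. This profile is the package's standard small
benchmark: the same vocabulary, sentences, window geometry and pipeline,
with corpus sizes and epochs scaled so one complete three-modality run
takes on the order of a minute on a single CPU while every qualitative
ordering of interest (isolated-word vs. in-sentence degradation, recovery
after window retraining, LM benefit, fusion advantage) is preserved.
"""

from __future__ import annotations

from dataclasses import replace

from .augmentation import AugmentPlan
from .evaluate import ExperimentConfig
from .snn import EncoderConfig
from .synthetic import SynthConfig


def benchmark_synth_config(seed: int = 0) -> SynthConfig:
    """Scaled-down corpora: 16 repetitions per word, 12 per sentence."""
    return SynthConfig(n_word_reps=16, n_sentence_reps=12, seed=seed)


def benchmark_experiment_config(seed: int = 0,
                                modalities=("emg", "eeg", "fusion")) -> ExperimentConfig:
    """The standard small benchmark: full pipeline, scaled problem size."""
    return ExperimentConfig(
        synth=benchmark_synth_config(seed),
        encoder=EncoderConfig(epochs=6, seed=seed),
        # the fused encoder has ~2x the parameters of a unimodal one and
        # trains proportionally more slowly; give it a matching budget
        fusion_epochs=12,
        retrain_epochs=4,
        augment=AugmentPlan(per_recording_count=2, seed=seed),
        modalities=tuple(modalities),
        seed=seed,
    )


def fusion_stress_experiment_config(seed: int = 0) -> ExperimentConfig:
    """Benchmark variant with per-modality noise raised so each unimodal
    model makes independent errors - the regime where fusion should win."""
    cfg = benchmark_experiment_config(seed)
    return replace(cfg, synth=replace(cfg.synth, noise_sd_emg=1.5, noise_sd_eeg=1.8))
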