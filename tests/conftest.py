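import statistics

import numpy as np
import pytest

from psee import classify
from psee.energy import PSEEConfig, mean_psee_by_label, psee_profile
from psee.evaluate import confusion_counts, mcc
from psee.synthetic import SyntheticSpec, generate_dataset, generate_feature_table
from psee.tables import (
    load_asa_normalization,
    load_contact_energy_matrix,
    load_hydrophobicity,
)


@pytest.fixture(scope="session")
def matrix():
    return load_contact_energy_matrix()


@pytest.fixture(scope="session")
def asa_table():
    return load_asa_normalization()


@pytest.fixture(scope="session")
def hydro_table():
    return load_hydrophobicity()


@pytest.fixture(scope="session")
def synth_dataset():
    """Default synthetic dataset: 24 sequences, seed 7."""
    return generate_dataset(SyntheticSpec())


@pytest.fixture(scope="session")
def synth_summary(synth_dataset, asa_table, matrix):
    """Flattened PSEE profiles (CR 9) + labels + class-mean summary."""
    profiles, labels = [], []
    for record, asa, track in synth_dataset:
        p_bur = [
            1.0 - min(a / asa_table[aa], 1.0)
            for aa, a in zip(record.sequence, asa)
        ]
        profiles.extend(psee_profile(record.sequence, p_bur, PSEEConfig(), matrix))
        labels.extend(track.symbols)
    summary = mean_psee_by_label(profiles, labels)
    return profiles, labels, summary


@pytest.fixture(scope="session")
def ablation_results():
    """Held-out MCC of the full vs PSEE-ablated classifier, 3 seeded repeats.

    A compact dataset (10 sequences of 50-90 residues, seed 7) keeps the
    six SVM fits fast; splits are by whole sequence so windows never leak
    across the train/test boundary.
    """
    spec = SyntheticSpec(n_sequences=10, length_range=(50, 90), seed=7)
    dataset = generate_dataset(spec)
    schema = classify.default_schema()
    tables = generate_feature_table(dataset, schema, seed=7)

    def run_repeat(rep: int) -> dict[str, float]:
        rng = np.random.default_rng(7 + rep)
        order = rng.permutation(len(dataset))
        test_ids = set(order[: max(2, len(dataset) // 3)].tolist())
        out = {}
        for ablate in (False, True):
            sch = schema.without_psee() if ablate else schema
            Xtr, ytr, Xte, yte = [], [], [], []
            for k, ((record, _, track), table) in enumerate(zip(dataset, tables)):
                windowed = classify.assemble_windowed_features(
                    table[list(sch.feature_names)].to_numpy(), sch
                )
                if k in test_ids:
                    Xte.append(windowed)
                    yte.extend(track.symbols)
                else:
                    Xtr.append(windowed)
                    ytr.extend(track.symbols)
            model = classify.train_disorder_classifier(
                np.vstack(Xtr), ytr, seed=7 + rep
            )
            prob = classify.disorder_probability(model, np.vstack(Xte))
            predicted = ["D" if p >= 0.5 else "O" for p in prob]
            out["ablated" if ablate else "full"] = mcc(
                confusion_counts(predicted, list(yte))
            )
        return out

    repeats = [run_repeat(r) for r in range(3)]
    return {
        "repeats": repeats,
        "median_full": statistics.median(r["full"] for r in repeats),
        "median_ablated": statistics.median(r["ablated"] for r in repeats),
    }
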