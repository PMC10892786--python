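"""Extract the 52-feature epoch vectors and apply ±1-epoch shifting.

Writes a synthetic EDF pair to a temporary directory, reads it back through
the EDF layer (stage harmonisation + wake trimming included), extracts the
feature matrix and shows how shifting turns 52 columns into 154.
"""

import tempfile
from pathlib import Path

from somnoboost import make_fixture, shift_features
from somnoboost.pipeline import features_from_manifest

with tempfile.TemporaryDirectory() as tmp:
    manifest = make_fixture(
        n_subjects=1, epochs_per_subject=80, preset="easy", seed=3, out_dir=tmp
    )
    print("fixture files:", sorted(p.name for p in Path(tmp).iterdir()))

    base = features_from_manifest(manifest, shift=False)
    print(f"\nbase matrix: {base.shape[0]} epochs × "
          f"{base.shape[1] - 3} features (+3 metadata columns)")
    print("first feature columns:", list(base.columns[:8]), "...")

    shifted = shift_features(base)
    n_feat = shifted.shape[1] - 3
    print(f"after ±1-epoch shifting: {n_feat} features "
          f"(3 × 51 shifted/original + age)")
    print("example shifted columns:", [c for c in shifted.columns if "rms" in c])

    sample = base[["epoch", "stage", "rms", "power_delta", "sample_entropy"]].head(5)
    print("\nfirst epochs:\n", sample.to_string(index=False))
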