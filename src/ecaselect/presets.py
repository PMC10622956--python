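"""Optional per-subject hyperparameter presets.

Tuned values (TPE search) for the nine subjects of the standard four-class
motor-imagery benchmark, before and after channel selection.  They are
shipped as a convenience for users working with that dataset; nothing in the
package depends on them.
"""

from __future__ import annotations

from .network import Hyperparameters

__all__ = ["subject_preset", "SUBJECT_PRESETS"]

# subject -> (before-selection, after-selection) settings:
# (dropout, optimizer, learning rate, batch size, weight decay)
SUBJECT_PRESETS: dict[int, tuple[dict, dict]] = {
    1: (
        dict(dropout_rate=0.5, optimizer="AdamW", learning_rate=1.049e-3, batch_size=32, weight_decay=1e-5),
        dict(dropout_rate=0.2, optimizer="AdamW", learning_rate=8.234e-5, batch_size=16, weight_decay=1e-2),
    ),
    2: (
        dict(dropout_rate=0.3, optimizer="AdamW", learning_rate=1.922e-4, batch_size=4, weight_decay=1e-3),
        dict(dropout_rate=0.5, optimizer="AdamW", learning_rate=2.852e-3, batch_size=16, weight_decay=1e-3),
    ),
    3: (
        dict(dropout_rate=0.5, optimizer="Adagrad", learning_rate=9.036e-3, batch_size=8, weight_decay=1e-4),
        dict(dropout_rate=0.6, optimizer="AdamW", learning_rate=2.362e-2, batch_size=4, weight_decay=1e-2),
    ),
    4: (
        dict(dropout_rate=0.4, optimizer="AdamW", learning_rate=2.940e-4, batch_size=16, weight_decay=1e-4),
        dict(dropout_rate=0.3, optimizer="AdamW", learning_rate=2.159e-4, batch_size=8, weight_decay=1e-2),
    ),
    5: (
        dict(dropout_rate=0.4, optimizer="AdamW", learning_rate=5.330e-5, batch_size=4, weight_decay=1e-4),
        dict(dropout_rate=0.2, optimizer="AdamW", learning_rate=6.413e-4, batch_size=16, weight_decay=1e-4),
    ),
    6: (
        dict(dropout_rate=0.4, optimizer="AdamW", learning_rate=2.639e-4, batch_size=4, weight_decay=1e-4),
        dict(dropout_rate=0.4, optimizer="AdamW", learning_rate=6.915e-4, batch_size=16, weight_decay=1e-4),
    ),
    7: (
        dict(dropout_rate=0.7, optimizer="Adagrad", learning_rate=1.181e-2, batch_size=16, weight_decay=1e-2),
        dict(dropout_rate=0.3, optimizer="AdamW", learning_rate=3.533e-4, batch_size=8, weight_decay=1e-5),
    ),
    8: (
        dict(dropout_rate=0.3, optimizer="Adagrad", learning_rate=2.276e-2, batch_size=16, weight_decay=1e-5),
        dict(dropout_rate=0.5, optimizer="AdamW", learning_rate=1.058e-3, batch_size=4, weight_decay=1e-2),
    ),
    9: (
        dict(dropout_rate=0.4, optimizer="AdamW", learning_rate=5.243e-4, batch_size=16, weight_decay=1e-2),
        dict(dropout_rate=0.2, optimizer="AdamW", learning_rate=2.092e-3, batch_size=16, weight_decay=1e-2),
    ),
}


def subject_preset(subject: int, after_selection: bool = False, **overrides) -> Hyperparameters:
    """Hyperparameters preset for a subject (1-9), before or after selection."""
    if subject not in SUBJECT_PRESETS:
        raise KeyError(f"no preset for subject {subject}; choose 1-9")
    base = dict(SUBJECT_PRESETS[subject][1 if after_selection else 0])
    base.update(overrides)
    return Hyperparameters(**base)
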