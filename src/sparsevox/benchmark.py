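"""The desk-scale benchmark: fixed study conditions for both tasks.

One module owns the benchmark so the test suite and the acceptance script
run exactly the same conditions: 60 training / 20 held-out synthetic shells,
completion at 32³ and super-resolution at 16³→32³, the ch1 channel list,
additive encoder–decoder skips (see docs/methods.md for why desk scale needs
them), and fixed epoch budgets.  All randomness derives from one seed.
"""

from __future__ import annotations

import numpy as np

from .metrics import dsc
from .synth import make_completion_samples, make_superres_samples
from .train import TrainConfig, predict, train_completion, train_superres

N_TRAIN = 60
N_TEST = 20
COMPLETION_RESOLUTION = 32
SUPERRES_LO, SUPERRES_HI = 16, 32
CH_DESK = (8, 8, 16, 16, 32, 32, 64)
COMPLETION_EPOCHS = 60
COMPLETION_LR_STEP = 40
SUPERRES_EPOCHS = 24
LEARNING_RATE = 1e-3
RESTART_EVERY = 4  # optimizer warm restarts (see docs/methods.md)


def derive_seeds(seed: int, n: int = 4) -> list[int]:
    """n reproducible sub-seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def completion_benchmark(seed: int = 0, verbose: bool = False) -> dict:
    """Train the completion recipe and evaluate on the held-out split.

    Returns mean test DSC of the trained net, the defective input's own DSC
    (the no-learning baseline), and bookkeeping counts.
    """
    s_train, s_test, s_net, _ = derive_seeds(seed)
    train = make_completion_samples(N_TRAIN, resolution=COMPLETION_RESOLUTION, seed=s_train)
    test = make_completion_samples(N_TEST, resolution=COMPLETION_RESOLUTION, seed=s_test)
    cfg = TrainConfig(
        task="completion",
        ch=CH_DESK,
        epochs=COMPLETION_EPOCHS,
        lr=LEARNING_RATE,
        lr_step=COMPLETION_LR_STEP,
        restart_every=RESTART_EVERY,
        seed=s_net,
        additive_skips=True,
        augment_orientations=True,
    )
    net, history = train_completion(train, cfg)
    input_dsc = float(np.mean([dsc(s.defective, s.complete) for s in test]))
    test_dsc = float(
        np.mean([dsc(predict(net, s.defective, cfg), s.complete) for s in test])
    )
    out = {
        "test_dsc": test_dsc,
        "input_dsc": input_dsc,
        "final_loss": history[-1]["loss"],
        "n_train": N_TRAIN,
        "n_test": N_TEST,
        "resolution": COMPLETION_RESOLUTION,
    }
    if verbose:
        print(
            f"completion: test DSC {test_dsc:.5f} vs defective-input DSC {input_dsc:.5f}"
        )
    return out


def superres_benchmark(seed: int = 0, verbose: bool = False) -> dict:
    """Train the super-resolution recipe and evaluate on the held-out split.

    Returns mean test DSC of the trained net and of the trilinear
    interpolation baseline (the up-scaled input itself).
    """
    s_train, s_test, s_net, _ = derive_seeds(seed + 1)
    train = make_superres_samples(N_TRAIN, res_lo=SUPERRES_LO, res_hi=SUPERRES_HI, seed=s_train)
    test = make_superres_samples(N_TEST, res_lo=SUPERRES_LO, res_hi=SUPERRES_HI, seed=s_test)
    cfg = TrainConfig(
        task="superres",
        ch=CH_DESK,
        epochs=SUPERRES_EPOCHS,
        lr=LEARNING_RATE,
        restart_every=RESTART_EVERY,
        seed=s_net,
        additive_skips=True,
    )
    net, history = train_superres(train, cfg)
    interp_dsc = float(np.mean([dsc(p.upscaled, p.target) for p in test]))
    test_dsc = float(
        np.mean([dsc(predict(net, p.upscaled, cfg), p.target) for p in test])
    )
    out = {
        "test_dsc": test_dsc,
        "interpolation_dsc": interp_dsc,
        "final_loss": history[-1]["loss"],
        "n_train": N_TRAIN,
        "n_test": N_TEST,
        "resolution": f"{SUPERRES_LO}->{SUPERRES_HI}",
    }
    if verbose:
        print(
            f"superres: test DSC {test_dsc:.5f} vs interpolation DSC {interp_dsc:.5f}"
        )
    return out
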