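"""Scaled synthetic-cohort experiments exercising the full learning stack.

CPU-sized versions of the study's two headline comparisons, run on
synthetic cohorts whose class separability is controlled by `effect_size`:

* label recovery — supervised training on a strongly separable cohort
  must recover the stimulus level in held-out subjects, while an
  effect-free cohort must stay at chance;
* self-supervised fine-tuning — training the adaptive-prior VAE system on
  non-augmented data, generating 25% pseudo-labeled samples from the
  learned priors and fine-tuning on only those, compared against the same
  system trained on the 9x shift-augmented data, plus a fixed
  standard-normal-prior ablation.

The scaled conditions (10 subjects x 5 levels x 10 repetitions, 1 s
windows at 256 Hz, latent width 16, learning rate 3e-3, KL weights
beta = 1, prior window tau = 50) are fixed design choices for this problem
size; docs/methods.md discusses how they relate to the full-scale presets.
"""

from __future__ import annotations

import numpy as np

from . import avae_ssl, ddcae, evaluation, preprocess, synthetic

#: frozen scaled study conditions
N_SUBJECTS = 10
N_LEVELS = 5
REPS_PER_LEVEL = 10
HIGH_EFFECT = 5.0
WINDOW_S = 1.0
ETA = 16
LR = 3e-3
BATCH = 20
SUP_EPOCHS = 30
NULL_EPOCHS = 15
SSL_PRETRAIN_EPOCHS = 30
SSL_FINETUNE_EPOCHS = 10
AUG_EPOCHS = 8
SCALED_BETA = 1.0
SCALED_EMA_DECAY = 0.98


def build_cohort(effect_size: float, cohort_seed: int, augmented: bool = False):
    """Binary-task segments (baseline vs strongest level) of a scaled cohort."""
    spec = synthetic.CohortSpec(
        n_subjects=N_SUBJECTS, n_levels=N_LEVELS,
        reps_per_level=REPS_PER_LEVEL, effect_size=effect_size,
        seed=cohort_seed,
    )
    recs = synthetic.generate_cohort(spec)
    ds = preprocess.preprocess_recordings(
        recs, dataset="biovid", window_s=WINDOW_S, with_augmentation=augmented
    )
    return ds.select(np.isin(ds.y, [0, N_LEVELS - 1]))


def _model_cfg(ds, seed: int) -> ddcae.ModelConfig:
    return ddcae.preset(
        "biovid", "binary", m=ds.m, modalities=ds.modalities, eta=ETA,
        attention=True, lr=LR, batch_size=BATCH, epochs=SUP_EPOCHS, seed=seed,
    )


def _split_fold(ds, test_subject, eval_ds=None):
    train = ds.select(ds.subject != test_subject)
    test = (eval_ds or ds).select((eval_ds or ds).subject == test_subject)
    train, stats = preprocess.normalize(train)
    return train, preprocess.apply_scaling(test, stats)


def supervised_label_recovery(cohort_seed: int, effect_size: float,
                              n_folds: int = 3,
                              epochs: int | None = None) -> dict:
    """LOSO accuracy of the supervised model over the first `n_folds` folds."""
    ds = build_cohort(effect_size, cohort_seed)
    folds = evaluation.loso_folds(ds)[:n_folds]
    results = []
    for k, (_, test_subject) in enumerate(folds):
        train, test = _split_fold(ds, test_subject)
        cfg = _model_cfg(ds, seed=cohort_seed * 13 + k)
        model, _ = ddcae.train_supervised(
            train, cfg, epochs=epochs if epochs is not None else SUP_EPOCHS
        )
        results.append(evaluation.FoldResult(
            test_subject, test.y, model.predict(test.X),
            classes=model.classes_,
        ))
    report = evaluation.aggregate_report(results)
    return {
        "accuracy": report["accuracy"]["mean"],
        "per_fold": [r.metrics["accuracy"] for r in results],
        "n_test": int(sum(len(r.y_true) for r in results)),
    }


def _ssl_cfgs(seed: int, fixed_prior: bool):
    return avae_ssl.SSLConfig(
        beta1=SCALED_BETA, beta2=SCALED_BETA, beta3=SCALED_BETA,
        ema_decay=SCALED_EMA_DECAY, gen_fraction=0.25,
        pretrain_epochs=SSL_PRETRAIN_EPOCHS,
        finetune_epochs=SSL_FINETUNE_EPOCHS,
        fixed_prior=fixed_prior, seed=seed,
    )


def ssl_comparison(cohort_seed: int, seeds=(0, 1, 2)) -> dict:
    """Three-arm comparison, one LOSO fold per seed (rotating test subject).

    Arms: self-trained adaptive-prior VAE (pretrain on originals, fine-tune
    on 25% self-generated), the same with a fixed standard-normal prior,
    and the same system trained on the 9x shift-augmented data.
    """
    ds = build_cohort(HIGH_EFFECT, cohort_seed)
    ds_aug = build_cohort(HIGH_EFFECT, cohort_seed, augmented=True)
    subjects = ds.subjects()
    out = {"self_trained": [], "fixed_prior": [], "augmented": []}
    for s in seeds:
        test_subject = subjects[s % len(subjects)]
        train, test = _split_fold(ds, test_subject)
        train_aug, test_aug = _split_fold(ds_aug, test_subject, eval_ds=ds)
        cfg = _model_cfg(ds, seed=s)
        for arm, fixed in (("self_trained", False), ("fixed_prior", True)):
            model = avae_ssl.AdaptiveVAESystem(cfg, _ssl_cfgs(100 + s, fixed))
            model.fit(train)
            K = int(np.ceil(0.25 * len(train)))
            model.fine_tune(model.generate(K))
            out[arm].append(float((model.predict(test.X) == test.y).mean()))
        model = avae_ssl.AdaptiveVAESystem(cfg, _ssl_cfgs(100 + s, False))
        model.fit(train_aug, epochs=AUG_EPOCHS)
        out["augmented"].append(
            float((model.predict(test_aug.X) == test_aug.y).mean())
        )
    return {arm: {"mean": float(np.mean(v)), "per_seed": v}
            for arm, v in out.items()}
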