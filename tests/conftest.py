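import numpy as np
import pytest

import tcrdyn as t


@pytest.fixture(scope="session")
def vocab():
    return t.build_vocabulary()


@pytest.fixture(scope="session")
def small_pools():
    """A small template-structured repertoire shared by read-only tests."""
    spec = t.SyntheticDatasetSpec(n_cdr3=200, n_antigen=60, seed=17)
    antigens, cdr3s = t.generate_repertoire(spec)
    return spec, antigens, cdr3s


def _study_config():
    """The tiny-study conditions shipped with the package: tiny preset,
    shared-kmer rule, 30 pretraining epochs with a checkpoint every 5, and a
    5-split finetuning sweep (configs/tiny.yaml)."""
    from pathlib import Path

    from tcrdyn.cli import ExperimentConfig

    configs = Path(__file__).resolve().parent.parent / "configs"
    return ExperimentConfig.from_yaml(configs / "tiny.yaml", {"outdir": "unused"})


@pytest.fixture(scope="session")
def tiny_study():
    """Run the full tiny pretraining-dynamics study once per session.

    Returns (loss_curve, sweep_result, series, datasets); several acceptance
    checks consume different aspects of the same run.
    """
    from tcrdyn.cli import derive_stage_seed
    from tcrdyn.model import init_model

    cfg = _study_config()
    spec = cfg.dataset_spec()
    antigens, cdr3s = t.generate_repertoire(spec)
    dataset = t.build_finetune_dataset(
        antigens, cdr3s, spec.binding_rule, n_positive=cfg.n_positive,
        neg_ratio=cfg.neg_ratio, seed=derive_stage_seed(cfg.seed, "finetune_data"),
    )
    pt_seed = derive_stage_seed(cfg.seed, "pretrain")
    corpus = t.build_pretrain_corpus(antigens, cdr3s, cfg.corpus_mode, seed=pt_seed)
    schedule = t.PretrainSchedule(
        epochs=cfg.pretrain_epochs, batch_size=cfg.pretrain_batch_size,
        learning_rate=cfg.pretrain_lr, checkpoint_every=cfg.checkpoint_every,
        eval_fraction=cfg.eval_fraction, seed=pt_seed,
    )
    state = init_model(cfg.model_config(), seed=pt_seed)
    series, curve = t.pretrain(state, corpus, schedule, save_initial=True)
    plan = t.FinetunePlan(
        n_splits=cfg.n_splits, epochs=cfg.finetune_epochs,
        batch_size=cfg.finetune_batch_size, learning_rate=cfg.finetune_lr,
        seed=derive_stage_seed(cfg.seed, "sweep"),
    )
    result = t.sweep(series, {"dataset_0": dataset}, plan, checkpoint_stride=cfg.sweep_stride)
    return curve, result, series, {"dataset_0": dataset}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# -- shared CLI pipeline runs (mini scale) ----------------------------------

CONFIGS_DIR = None  # resolved lazily to keep conftest import-light


def _mini_config_path(tmp_path):
    from pathlib import Path

    import yaml

    configs = Path(__file__).resolve().parent.parent / "configs"
    raw = yaml.safe_load((configs / "mini.yaml").read_text())
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(raw))
    return path


def run_cli(args):
    from click.testing import CliRunner

    from tcrdyn.cli import main

    result = CliRunner().invoke(main, args, catch_exceptions=False)
    assert result.exit_code == 0, result.output
    return result


def pipeline_artifacts(outdir):
    """Deterministic text/weight artifacts of a run (excludes logs, plots and
    the resolved config, which embeds the output path)."""
    names = sorted(
        p.relative_to(outdir).as_posix()
        for p in outdir.rglob("*")
        if p.is_file() and p.suffix in (".csv", ".json", ".fasta", ".txt", ".bin")
    )
    return {n: (outdir / n).read_bytes() for n in names}


@pytest.fixture(scope="session")
def mini_run(tmp_path_factory):
    """One full run-all of the mini configuration."""
    tmp = tmp_path_factory.mktemp("mini")
    config = _mini_config_path(tmp)
    outdir = tmp / "run"
    run_cli(["run-all", "--config", str(config), "--outdir", str(outdir)])
    return config, outdir


@pytest.fixture(scope="session")
def mini_rerun(mini_run, tmp_path_factory):
    """A second run-all with the identical config and seed."""
    config, _ = mini_run
    outdir = tmp_path_factory.mktemp("mini2") / "run"
    run_cli(["run-all", "--config", str(config), "--outdir", str(outdir)])
    return outdir
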