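combos:
  d1-mu1e4:
    b: 0.0
    burn_in_generations: 20000
    delta: 1.0
    export_generations:
    - 0
    - 100
    - 500
    - 1000
    - 3000
    - 5000
    grid_height: 100
    grid_width: 100
    mu: 0.0001
    n_loci: 20
    n_replicates: 25
    sample_size: 200
    seed: 0
  d1-mu2.5e5:
    b: 0.0
    burn_in_generations: 80000
    delta: 1.0
    export_generations:
    - 0
    - 100
    - 500
    - 1000
    - 3000
    - 5000
    grid_height: 100
    grid_width: 100
    mu: 2.5e-05
    n_loci: 20
    n_replicates: 25
    sample_size: 200
    seed: 0
  d11-mu1e4:
    b: 0.0
    burn_in_generations: 20000
    delta: 11.0
    export_generations:
    - 0
    - 100
    - 500
    - 1000
    - 3000
    - 5000
    grid_height: 100
    grid_width: 100
    mu: 0.0001
    n_loci: 20
    n_replicates: 25
    sample_size: 200
    seed: 0
  d11-mu1e4-b03:
    b: 0.03
    burn_in_generations: 20000
    delta: 11.0
    export_generations:
    - 0
    - 100
    - 500
    - 1000
    - 3000
    - 5000
    grid_height: 100
    grid_width: 100
    mu: 0.0001
    n_loci: 20
    n_replicates: 25
    sample_size: 200
    seed: 0
  d11-mu2.5e5:
    b: 0.0
    burn_in_generations: 80000
    delta: 11.0
    export_generations:
    - 0
    - 100
    - 500
    - 1000
    - 3000
    - 5000
    grid_height: 100
    grid_width: 100
    mu: 2.5e-05
    n_loci: 20
    n_replicates: 25
    sample_size: 200
    seed: 0
methods:
  monmonier:
    distance: residual
    n_barriers: 4
  wombling: {}
n_replicates: 25
output_dir: benchmark_out
seed: 1
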