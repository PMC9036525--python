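# File formats

All on-disk artifacts are tab-separated text (TSV, never CSV — immune to
locale decimal separators). Floats are written with Python's shortest
round-trip representation, so write → read is lossless bit-for-bit.

## Work set TSV (`write_workset` / `read_workset`)

Metadata preamble, one `# key<TAB>value` line each, in fixed order:
`system`, `direction`, `temperature`, `protocol_name`, `n_switch`,
`n_replicate`, `blocksize`, `stride`, `t_total`.

Then a header line and one row per switch, fixed column order:

    direction  block  within_index  global_index  work_kcal_mol
    chi<k>_pre_deg  chi<k>_post_deg  (for k = 1..n tracked dihedrals)
    seed

Backward work values are stored as generated (high→low direction).

## Restart pool TSV (`write_pool` / `read_pool`)

Preamble: `# level`, `# save_stride`. Columns:

    block  snapshot_index  chi_deg  q1_deg ...  v_chi_deg_fs  v_q1_deg_fs ...

Snapshots appear in save order within each block.

## Run configuration (YAML)

Top-level keys: `system`, `seed`, `temperature`, `outlier_k`,
`output_dir`, `dihedral_labels`, `surfaces` (`low`/`high`, each with
`dihedral_terms` as `[amplitude, multiplicity, phase]` triples,
`bath_stiffness`, `offset`, `coupling`), `langevin` (`friction`,
`timestep`, `mass`), `pool` (`low`/`high`, each with `run_length`,
`save_stride`, `burn_in`, `randomize_start`, `start_distribution`),
`protocols` (list of `name`, `n_switch`, `n_replicate`), `reduced`
(`from`, `keep_per_block`). Unknown keys are rejected; all validation
errors are reported at once.
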