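# End-to-end demo: synthetic tissue with a planted clustered giant pattern,
# a 100-member randomization ensemble, and the pooled clustering test.
seed: 17
stages:
  - name: synth
    params:
      n_cells: 150
      size: 200
      plant:
        mode: clustered
        k: 15
    outputs: [tissue.tif, cells.csv]
  - name: randomize
    params:
      n: 100
    inputs: [tissue.tif]
    outputs: []
  - name: stats
    inputs: [tissue.tif, cells.csv]
    outputs: [result.json]
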