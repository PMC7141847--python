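# Full demonstration benchmark for the command line:
#   pipebench simulate --config examples/demo_config.yaml
#   pipebench run      --config examples/demo_config.yaml
#   pipebench time     --config examples/demo_config.yaml
seed: 7
workers: 1
output_dir: pipebench_out
datasets:
  - name: plate_like
    simulate: {n_genes: 200, n_cells: 120, n_groups: 3, lib_size_mu: 5000}
  - name: droplet_like
    simulate: {n_genes: 200, n_cells: 120, n_groups: 3, lib_size_mu: 500}
steps:
  - step: norm_method
    methods: [none, cpm, logcpm, medratio]
  - step: impute_method
    methods: [none, {name: knn_smooth, params: {k: 5}}, magic_lite]
  - step: cluster_method
    methods: [kmeans, hclust_ward, graph_louvain_lite]
metrics: [ari]
sizes: [30, 60, 120]   # used by `pipebench time` for the scaling series
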