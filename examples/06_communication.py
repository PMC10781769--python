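"""Recover planted ligand->TF couplings and a planted LR interaction.

Runs the default communication benchmark: 4 samples with 3 planted spatial
ligand->TF effects among 10 ligands x 5 TFs, then a consensus ranking of a
planted ligand-receptor pair among 200 decoys, and finally a shortest-path
signaling network from the toy prior.
"""

from spotflow.benchmarks import communication_benchmark, lr_benchmark
from spotflow.communication import selected_pairs, shortest_path_network

bench = communication_benchmark(seed=0)
print("planted pairs:", bench["planted_pairs"])
print(f"min planted aggregated importance: {bench['min_planted_importance']:.2f} "
      "(selection threshold 1.0)")
print(f"null pairs above threshold: {100 * bench['null_exceedance']:.1f}%")
print(f"planted-vs-null ranking AUC: {bench['auc']:.2f}")

lr = lr_benchmark(seed=0)
print(f"planted LR pair aggregate rank: {lr['planted_rank']:.4f} "
      f"among {lr['n_candidates']} candidates (selected when < 0.01)")

# connect the top LR hit to a planted TF through the signed PPI graph
top = lr.get("table").iloc[0]
import pandas as pd

hits = pd.DataFrame({"ligand": [top["ligand"]], "receptor": [top["receptor"]],
                     "selected": [True]})
from spotflow.synthio import make_toy_prior

prior = make_toy_prior(n_tfs=5, n_ligands=10, seed=0)
prior = type(prior)(
    ligands=prior.ligands | {str(top["ligand"])},
    lr_pairs=prior.lr_pairs + ((str(top["ligand"]), str(top["receptor"])),),
    ppi_edges=prior.ppi_edges + ((str(top["receptor"]), "TF00", 1),),
    regulons=prior.regulons,
    pathway_weights=prior.pathway_weights,
)
net = shortest_path_network(prior, hits, [(str(top["ligand"]), "TF00")])
print(f"signaling network: {net.graph.number_of_nodes()} nodes, "
      f"{net.graph.number_of_edges()} edges, {len(net.unreachable)} unreachable pairs")
# Importances are z-scores across ligands per TF, so a planted coupling well
# above 1 stands out against the 10-ligand background.
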