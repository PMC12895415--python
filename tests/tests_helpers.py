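"""Shared helpers for building encoder batches from SMILES in tests."""

import numpy as np

from zindelta.descriptors import molecular_graph
from zindelta.networks import GraphBatch


def build_batch(smiles_list, node_channels, e_low):
    nodes_list, src_list, dst_list, ef, mol_idx = [], [], [], [], []
    off = 0
    for b, smi in enumerate(smiles_list):
        nodes, src, dst, efeat = molecular_graph(smi)
        if node_channels == 45:
            nodes = np.concatenate([nodes, np.zeros((len(nodes), 4))], axis=1)
        nodes_list.append(nodes)
        src_list.append(src + off)
        dst_list.append(dst + off)
        ef.append(efeat)
        mol_idx.append(np.full(len(nodes), b))
        off += len(nodes)
    e = np.asarray(e_low, float)
    return GraphBatch(
        node_x=np.concatenate(nodes_list),
        edge_src=np.concatenate(src_list).astype(int),
        edge_dst=np.concatenate(dst_list).astype(int),
        edge_attr=np.concatenate(ef),
        node_mol=np.concatenate(mol_idx).astype(int),
        n_mols=len(smiles_list),
        e_low=e,
        e_low_z=e[:, None],
        mordf=np.zeros((len(smiles_list), 726)),
        mfp=np.zeros((len(smiles_list), 2048)),
    )
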