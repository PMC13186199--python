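aa_properties.csv — 13 per-residue scalar properties used for the
delta-AAP block of the local mutation descriptor. Columns (raw values;
z-score-normalised across the 20 residues at load time):

  hydrophobicity_kd   Kyte–Doolittle hydropathy index
  molecular_weight    free amino-acid molecular weight (Da)
  vdw_volume          side-chain van der Waals volume (A^3)
  polarity_grantham   Grantham polarity
  isoelectric_point   amino-acid pI
  net_charge_ph7      approximate side-chain charge at pH 7
  hbond_donors        side-chain hydrogen-bond donor count
  hbond_acceptors     side-chain hydrogen-bond acceptor count
  flexibility         Vihinen normalised flexibility index
  helix_propensity    Chou–Fasman P(alpha)
  sheet_propensity    Chou–Fasman P(beta)
  max_asa             theoretical maximum solvent-accessible area (A^2)
  aromaticity         aromatic side-chain indicator (F, W, Y, H)

Users may substitute their own 20-row x 13-column table with the same
header shape; the loader only requires 13 numeric columns over the 20
standard residues.
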