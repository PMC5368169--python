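# RING subtype classification rules.
#
# A canonical RING zinc-binding domain has eight metal-ligand positions
# coordinating two zinc ions.  The subtype is read from the residues at the
# two variable ligand positions 4 and 5 when the remaining six positions are
# canonical cysteines; otherwise the class is named after the non-canonical
# substituting residue at any metal position.  Edit this file to align with
# a revised published scheme.
pair_classes:          # (position 4, position 5) -> class, rest all Cys
  "H,C": HC            # C3HC4
  "H,H": H2            # C3H2C3
  "C,H": v             # vRING (CH)
  "C,C": C2
substituent_classes:   # residue appearing at any metal position -> class
  D: D
  S: S/T
  T: S/T
  G: G
fallback: non-canonical
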