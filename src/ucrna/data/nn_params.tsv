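# Nearest-neighbor duplex parameters, kcal/mol at 37 C.
# Single source of truth for the intermolecular duplex energy model.
#
# init                : duplex initiation penalty.
# loop <size> <dG>    : penalty for an interior loop/bulge with <size>
#                       total unpaired nucleotides between consecutive
#                       pairs (both strands combined); sizes above the
#                       largest listed entry are disallowed.
# stack <P> <Q> <dG>  : stacking term for the step 5'-p1 q1-3' paired
#                       with 3'-p2 q2-5', where P = p1p2 and Q = q1q2
#                       name the two base pairs (first letter on the
#                       5'->3' strand).  Watson-Crick values follow the
#                       Turner 2004 set; GU wobble values are curated
#                       approximations obeying nearest-neighbor strand
#                       symmetry stack(P,Q) = stack(rev Q, rev P).
#                       Absolute energies from this table are not
#                       claimed to match ViennaRNA output.
init	4.09
loop	1	3.80
loop	2	2.80
loop	3	3.20
loop	4	3.60
stack	AU	AU	-0.93
stack	AU	UA	-1.10
stack	AU	CG	-2.24
stack	AU	GC	-2.08
stack	AU	GU	-1.30
stack	AU	UG	-1.40
stack	UA	AU	-1.33
stack	UA	UA	-0.93
stack	UA	CG	-2.35
stack	UA	GC	-2.11
stack	UA	GU	-1.00
stack	UA	UG	-0.80
stack	CG	AU	-2.11
stack	CG	UA	-2.08
stack	CG	CG	-3.26
stack	CG	GC	-2.36
stack	CG	GU	-2.10
stack	CG	UG	-1.40
stack	GC	AU	-2.35
stack	GC	UA	-2.24
stack	GC	CG	-3.42
stack	GC	GC	-3.26
stack	GC	GU	-2.20
stack	GC	UG	-2.50
stack	GU	AU	-0.80
stack	GU	UA	-1.40
stack	GU	CG	-2.50
stack	GU	GC	-1.40
stack	GU	GU	0.50
stack	GU	UG	-0.50
stack	UG	AU	-1.00
stack	UG	UA	-1.30
stack	UG	CG	-2.20
stack	UG	GC	-2.10
stack	UG	GU	-0.60
stack	UG	UG	0.50
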