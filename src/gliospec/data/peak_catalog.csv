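shift_cm1,assignment,novel,previously_described,tumor_direction
431,Cholesterol/cholesterol ester,true,false,down
450,Ring torsion of phenyl,false,false,unknown
457,Proteins and cholesterol,false,true,unknown
460,Undefined,false,false,unknown
474,Glycogen and polysaccharides,false,false,unknown
478,Polysaccharides,false,false,unknown
495,Undefined,false,false,unknown
498,Nucleic acids/nucleotides,true,false,up
502,Undefined,false,false,unknown
517,Undefined,false,false,unknown
524,S-S disulfide stretching in proteins,true,false,unknown
540,n(S-S) trans-gauche-trans (amino acid cysteine),false,true,unknown
743,Heme (blood),true,false,unknown
754,Symmetric breathing of tryptophan,false,true,unknown
776,Phosphatidylinositol,true,false,unknown
780,Uracil based ring breathing mode,true,false,unknown
808,Undefined,false,false,unknown
817,C-C stretching/collagen assignment,true,false,unknown
825,Phosphodiester,true,false,unknown
826,"Tyr, proline",false,true,unknown
837,Undefined,false,false,unknown
850,Glycogen (high-grade tumors),false,true,up
853,Glycogen (high-grade tumors),false,true,unknown
875,Choline and phospholipids,true,false,unknown
880,"Tryptophan, d(ring)",false,true,up
881,Hydroxyproline and tryptophan (collagen); sterol ring stretch of cholesterol; asymmetric stretching of choline,false,true,unknown
883,rho(CH2) (protein assignment),false,true,unknown
894,Phosphodiester (nucleic acids),true,false,unknown
903,Undefined,false,true,unknown
916,Undefined,false,false,unknown
927,Undefined,false,true,unknown
928,Amino acids proline & valine (protein band),false,true,unknown
933,"Proline, hydroxyproline",true,false,unknown
934,C-C backbone (collagen assignment),false,true,unknown
941,Glycogen,true,false,unknown
950,Single bond stretching vibrations for the amino acids proline and valine and polysaccharides,false,true,unknown
954,Undefined,false,false,unknown
958,Stretching vibrations of PO4 in hydroxyapatite,false,true,unknown
963,Protein assignments,true,false,unknown
968,Lipids,true,false,down
975,Tricalcium phosphate Ca3(PO4) calcification seen in schwannoma and necrosis,true,false,unknown
977,Tricalcium phosphate Ca3(PO4) calcification seen in schwannoma and necrosis,false,true,unknown
1003,Ring breathing mode of phenylalanine of protein,false,true,up
1030,Phenylalanine (protein assignment) and collagen,false,true,unknown
1031,Phenylalanine (protein assignment),true,false,up
1035,Collagen,true,false,unknown
1036,Undefined,false,false,unknown
1122,Glycogen,false,true,unknown
1337,"Aliphatic amino acids, including tryptophan, nucleic acids. Glycogen in necrosis",false,true,up
1342,"Aliphatic amino acids, including tryptophan, nucleic acids. Glycogen",false,false,unknown
1578,"C-C stretch of protein, nucleic acids",false,true,unknown
1581,"C-C stretch of protein, nucleic acids",false,true,unknown
1583,"C-C stretch of protein, phenylalanine, nucleic acids",true,false,unknown
1603,Phenylalanine & tyrosine/Oxygenated haemoglobin,true,false,unknown
1604,"Cytosine, tyrosine, phenylalanine",false,true,unknown
1614,Aromatic amino acids (protein); tyrosine and proline,false,true,unknown
1616,C-C stretching mode of tyrosine & tryptophan,false,true,unknown
1657,Amide I (a-helix) (protein),false,true,unknown
1659,Amide I (a-helix),false,true,unknown
1660,Amide I band,false,true,unknown
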