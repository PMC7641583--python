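name,species,lambda_um,a_um,N,evidence_class,provenance
Wg,Drosophila,5.8,2.6,30,DT,synthetic placeholder - unverified; replace with literature values
Hh,Drosophila,8.0,2.6,30,DT,synthetic placeholder - unverified; replace with literature values
Bicoid,Drosophila,100.0,6.5,100,SDC,synthetic placeholder - unverified; replace with literature values
Dorsal,Drosophila,90.0,6.5,100,SDC,synthetic placeholder - unverified; replace with literature values
Dpp,Drosophila,20.0,2.6,40,multiple,synthetic placeholder - unverified; replace with literature values
Fgf8,zebrafish,197.0,5.0,60,SDC,synthetic placeholder - unverified; replace with literature values
Cyclops,zebrafish,15.0,8.0,40,multiple,synthetic placeholder - unverified; replace with literature values
Squint,zebrafish,30.0,8.0,40,multiple,synthetic placeholder - unverified; replace with literature values
Lefty1,zebrafish,150.0,8.0,40,SDC,synthetic placeholder - unverified; replace with literature values
Lefty2,zebrafish,190.0,8.0,40,SDC,synthetic placeholder - unverified; replace with literature values
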