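(Aque:1.0000,(Tadh:0.9500,((Hmag:0.5500,Nvec:0.5500):0.3500,(((Ctel:0.6000,Obim:0.6000):0.2000,(Cele:0.7500,(Amel:0.5000,(Agam:0.3500,Dmel:0.3500):0.1500):0.2500):0.0500):0.0500,(((Skow:0.3000,Pfla:0.3000):0.4000,Spur:0.7000):0.1000,(Bflo:0.7500,((Cint:0.2500,Csav:0.2500):0.4500,((Drer:0.4500,(Olat:0.4000,(Gacu:0.3500,(Trub:0.2500,Tnig:0.2500):0.1000):0.0500):0.0500):0.1500,(Xtro:0.5500,((Acar:0.4500,(Psin:0.4000,(Ggal:0.2000,Tgut:0.2000):0.2000):0.0500):0.0500,(Oana:0.4000,(Mdom:0.3500,((Lafr:0.2500,Dnov:0.2500):0.0500,(((Ocun:0.2400,(Mmus:0.1800,Rnor:0.1800):0.0600):0.0200,(Cjac:0.2000,(Mmul:0.1500,(Pabe:0.1200,(Ggor:0.0900,(Hsap:0.0600,Ptro:0.0600):0.0300):0.0300):0.0300):0.0500):0.0600):0.0200,(Eeur:0.2600,((Mluc:0.1800,Pvam:0.1800):0.0600,((Cfam:0.1500,Fcat:0.1500):0.0700,(Ecab:0.2000,Btau:0.2000):0.0200):0.0200):0.0200):0.0200):0.0200):0.0500):0.0500):0.1000):0.0500)amphibian-split:0.0500)teleost-tetrapod:0.1000)invertebrate-vertebrate:0.0500)cephalochordate-split:0.0500)ambulacrarian-split:0.0500)protostome-deuterostome:0.0500)cnidarian-split:0.0500)placozoan-split:0.0500)sponge-split;
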