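<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:ex="https://osipi.github.io/OSIPI_CAPLEX/llxml"
           targetNamespace="https://osipi.github.io/OSIPI_CAPLEX/llxml"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <!-- Lexicon-linked XML pipeline format.  A Pipeline holds at least one
       Process; a Process may nest further (different) Processes and carry
       InputQuantity, OutputQuantity, Model and SetEqual children in any
       order, each repeatable.  Name/code/unit consistency against the
       lexicon registry is checked by the semantic validator, not here. -->

  <xs:simpleType name="fitType">
    <xs:restriction base="xs:string">
      <xs:enumeration value="free"/>
      <xs:enumeration value="fixed"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="Pipeline">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="ex:Process" minOccurs="1" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="Process">
    <xs:complexType>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element ref="ex:Process"/>
        <xs:element ref="ex:InputQuantity"/>
        <xs:element ref="ex:OutputQuantity"/>
        <xs:element ref="ex:Model"/>
        <xs:element ref="ex:SetEqual"/>
      </xs:choice>
      <xs:attribute name="value" type="xs:string" use="required"/>
      <xs:attribute name="code" type="xs:string" use="required"/>
      <xs:attribute name="instance" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="InputQuantity">
    <xs:complexType>
      <xs:attribute name="value" type="xs:string" use="required"/>
      <xs:attribute name="code" type="xs:string" use="required"/>
      <xs:attribute name="unit" type="xs:string" use="required"/>
      <xs:attribute name="instance" type="xs:string"/>
      <xs:attribute name="type" type="ex:fitType"/>
      <xs:attribute name="numericValue" type="xs:double"/>
      <xs:attribute name="uncertainty" type="xs:double"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="OutputQuantity">
    <xs:complexType>
      <xs:attribute name="value" type="xs:string" use="required"/>
      <xs:attribute name="code" type="xs:string" use="required"/>
      <xs:attribute name="unit" type="xs:string" use="required"/>
      <xs:attribute name="instance" type="xs:string"/>
      <xs:attribute name="numericValue" type="xs:double"/>
      <xs:attribute name="uncertainty" type="xs:double"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="Model">
    <xs:complexType>
      <xs:attribute name="value" type="xs:string" use="required"/>
      <xs:attribute name="code" type="xs:string" use="required"/>
      <xs:attribute name="instance" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <!-- An explicit mathematical assumption: left quantity set equal to a
       second quantity or to a numeric literal. -->
  <xs:element name="SetEqual">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="ex:Quantity"/>
        <xs:choice>
          <xs:element ref="ex:Quantity"/>
          <xs:element ref="ex:Literal"/>
        </xs:choice>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="Quantity">
    <xs:complexType>
      <xs:attribute name="code" type="xs:string" use="required"/>
      <xs:attribute name="value" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="Literal">
    <xs:complexType>
      <xs:attribute name="numericValue" type="xs:double" use="required"/>
      <xs:attribute name="unit" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
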